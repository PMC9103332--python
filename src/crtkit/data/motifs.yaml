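# Degenerate protein motif definitions used by crtkit.protein.
#
# Pattern language: a literal residue matches itself, X matches any residue,
# (A/B/...) matches any residue listed in the group.  New motifs can be added
# here without code changes.
motifs:
  M1:
    pattern: "PXXIXDP(E/D)(A/D)XKP(E/D)DWD(D/E)"
    description: "Calreticulin P-domain proline-rich repeat 1 (17 aa)"
  M2:
    pattern: "GXWXXPXIXNPXYX"
    description: "Calreticulin P-domain proline-rich repeat 2 (14 aa)"
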
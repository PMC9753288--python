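# Default potential-pharmacophore-point (PPP) typing rules.
#
# Each type maps to a list of SMARTS patterns; an atom receives the type if
# it is the first atom of any match of any pattern.  An atom may carry zero,
# one or several types.  Rules are graph-only (no coordinates) and are meant
# to be overridden for specialized chemistries.
#
#   D  hydrogen-bond donor        N/O bearing at least one hydrogen
#   A  hydrogen-bond acceptor     any N/O (lone-pair semantics approximated)
#   P  positively ionizable       formal positive charge, or protonatable
#                                 sp3 amine not adjacent to a carbonyl
#   N  negatively ionizable       formal negative charge, or carboxylic acid
#                                 carbon (the acid group as a whole)
#   L  lipophilic                 carbon bonded only to carbon or hydrogen
D:
  - "[#7,#8;!H0]"
A:
  - "[#7,#8]"
P:
  - "[+,++]"
  - "[NX3;H2,H1,H0;!$([NX3]-[C,S,P]=[O,S,N]);!$([NX3]-a)]"
N:
  - "[-,--]"
  - "[CX3](=O)[OX2H1]"
L:
  - "[#6;!$([#6]~[!#6;!#1])]"
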
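>CX26_HUMAN P29033 Gap junction beta-2 protein (connexin 26), canonical, 226 aa; identity verified against the full published ProtParam profile of the native protein (MW, pI, charge counts, atom count, extinction coefficients, instability, aliphatic index, GRAVY) and all 22 legacy variant reference residues
MDWGTLQTILGGVNKHSTSIGKIWLTVLFIFRIMILVVAAKEVWGDEQADFVCNTLQPGC
KNVCYDHYFPISHIRLWALQLIFVSTPALLVAMHVAYRRHEKKRKFIKGEIKSEFKDIEE
IKTQKVRIEGSLWWTYTSSIFFRVIFEAAFMYVFYVMYDGFSMQRLVKCNAWPCPNTVDC
FVSRPTEKTVFTVFMIAVSGICILLNVTELCYLLIRYCSGKSKKPV
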
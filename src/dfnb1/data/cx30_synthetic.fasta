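>CX30_SYNTHETIC synthetic 261-aa surrogate for connexin 30 (GJB6, O95452): verified connexin-26 core (which conserves the variant reference residues Q57, E101 and R104) extended by an invented hydrophilic C-terminal tail to the documented Cx30 length. NOT the authentic O95452 sequence; used only for mutation application and delta comparisons, never for absolute Cx30 property values.
MDWGTLQTILGGVNKHSTSIGKIWLTVLFIFRIMILVVAAKEVWGDEQADFVCNTLQPGC
KNVCYDHYFPISHIRLWALQLIFVSTPALLVAMHVAYRRHEKKRKFIKGEIKSEFKDIEE
IKTQKVRIEGSLWWTYTSSIFFRVIFEAAFMYVFYVMYDGFSMQRLVKCNAWPCPNTVDC
FVSRPTEKTVFTVFMIAVSGICILLNVTELCYLLIRYCSGKSKKPVVRSAHEQHRSGSSK
SSGGRARPGDLAIDKSSHPLV
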
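>acp_like_synthetic | SYNTHETIC 81-residue hyperthermophilic-ACP-like sequence (not a deposited sequence); charged-residue composition 10 Glu / 11 Asp / 1 Arg / 8 Lys
MTSREEIFEKVKAIISEKLGVDEDQVNEDAKLTDDLGADSLALVALVMDFEAEFGNKDDT
DDLAKGSEVGKIVSYIEAKLA
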
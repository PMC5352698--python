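class	structures	adducts
SM	3384	2
Cer[NS]	3360	3
HexCer[NS]	3360	3
Cer[NDS]	1120	3
HexCer[NDS]	1120	3
Cer[AS]	3360	3
HexCer[AS]	3360	3
Cer[ADS]	1120	3
HexCer[ADS]	1120	3
Cer[BS]	3360	3
HexCer[BS]	3360	3
Cer[BDS]	1120	3
HexCer[BDS]	1120	3
Cer[EOS]	25536	3
HexCer[EOS]	25536	3
Cer[EODS]	8512	3
HexCer[EODS]	8512	3
Cer[AP]	2772	3
HexCer[AP]	2772	3
Cer[NP]	2772	3
HexCer[NP]	2772	3
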
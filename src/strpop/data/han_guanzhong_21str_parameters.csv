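statistic,D6S474,D12ATA63,D22S1045,D10S1248,D1S1677,D11S4463,D1S1627,D3S4529,D2S441,D6S1017,D4S2408,D19S433,D17S1301,D1GATA113,D18S853,D20S482,D14S1434,D9S1122,D2S1776,D10S1435,D5S2500
PD,0.8576,0.8858,0.8979,0.8906,0.7898,0.9034,0.7700,0.8775,0.9072,0.8828,0.8863,0.9437,0.8753,0.8091,0.8566,0.8975,0.8825,0.8852,0.8866,0.8969,0.8452
PIC,0.6476,0.6825,0.7243,0.7057,0.5527,0.7192,0.5325,0.6787,0.7299,0.6870,0.6994,0.7916,0.6672,0.5674,0.6713,0.7107,0.6822,0.6915,0.7040,0.7216,0.6386
PE,0.4199,0.4034,0.5790,0.5144,0.2822,0.4540,0.2865,0.4255,0.5082,0.4599,0.4717,0.5856,0.4540,0.2738,0.5462,0.5144,0.4658,0.4599,0.5207,0.5790,0.4599
TPI,1.6369,1.5805,2.3707,2.0221,1.2277,1.7628,1.2387,1.6566,1.9928,1.7857,1.8333,2.4123,1.7628,1.2061,2.1825,2.0221,1.8092,1.7857,2.0522,2.3707,1.7857
HO,0.6945,0.6836,0.7891,0.7527,0.5927,0.7164,0.5964,0.6982,0.7491,0.7200,0.7273,0.7927,0.7164,0.5855,0.7709,0.7527,0.7236,0.7200,0.7564,0.7891,0.7200
HE,0.7000,0.7278,0.7644,0.7468,0.6136,0.7582,0.5940,0.7219,0.7653,0.7329,0.7453,0.8147,0.7063,0.6285,0.7180,0.7475,0.7276,0.7352,0.7426,0.7586,0.6946
HWE_P,0.8062,0.0898,0.3622,0.8618,0.4535,0.0938,0.9664,0.3543,0.4888,0.5919,0.4591,0.3147,0.7501,0.1289,0.0567,0.8824,0.8448,0.5327,0.6383,0.2590,0.3848
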
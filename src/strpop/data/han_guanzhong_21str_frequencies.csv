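allele,D6S474,D12ATA63,D22S1045,D10S1248,D1S1677,D11S4463,D1S1627,D3S4529,D2S441,D6S1017,D4S2408,D19S433,D17S1301,D1GATA113,D18S853,D20S482,D14S1434,D9S1122,D2S1776,D10S1435,D5S2500
7,,,,,,,,,,0.0036,,,,0.5145,,,,,0.0018,,
8,,,,,,,,,,0.2236,0.2364,,0.0055,0.0091,,,,,,0.0236,
9,,,,,,0.0036,,,,,0.2945,,0.0236,,,0.0018,,0.0036,0.1200,0.0036,
9.1,,,,,,,,,0.0145,,,,,,,,,,,,
10,,,,,0.0091,,0.0291,,0.2309,0.3582,0.2964,,0.0655,0.0036,0.0091,0.0345,0.1073,0.0782,0.0673,0.0418,
10.1,,,,,,,,,0.0109,,,,,,,,,,,,
10.3,,,,,,,,,,,,,,,,,,,,0.0018,
11,,0.0018,0.2436,0.0109,,0.0018,0.0127,,0.3473,0.0364,0.1545,0.0036,0.1782,0.1691,0.4036,0.0109,0.1636,0.1709,0.2818,0.1618,
11.3,,,,,,,,,0.0309,,,,,,,,,,,,
12,,0.3327,0.0018,0.0673,0.0182,0.0509,0.0982,0.0018,0.2109,0.2818,0.0182,0.0418,0.4582,0.2782,0.0582,0.0673,0.0218,0.3182,0.3800,0.3473,
12.2,,,,,,,,,,,,0.0055,,,,,,,,,
12.3,,,,,,,,,,,,,0.0018,,,,,,,,
13,0.0018,0.0036,0.0091,0.3545,0.0891,0.2073,0.5564,0.1891,0.0200,0.0891,,0.2836,0.2109,0.0255,0.2436,0.2382,0.3091,0.3509,0.1164,0.2745,
13.2,,,,,,,,,,,,0.0564,,,,,,,,,
14,0.3745,0.0382,0.0109,0.2636,0.5309,0.3236,0.2927,0.2055,0.1200,0.0073,,0.2545,0.0509,,0.2309,0.3873,0.3709,0.0709,0.0327,0.1291,0.4073
14.1,,,,,,,,,0.0018,,,,,,,,,,,,
14.2,,,,,,,,,,,,0.1055,,,,,,,,,
15,0.3636,0.0018,0.2855,0.2200,0.3073,0.2855,0.0091,0.4182,0.0127,,,0.0709,0.0055,,0.0545,0.1855,0.0236,0.0036,,0.0145,
15.2,,,,,,,,,,,,0.1345,,,,,,,,,
16,0.1345,0.1600,0.2582,0.0691,0.0418,0.0964,0.0018,0.1564,,,,0.0182,,,,0.0745,0.0036,0.0036,,0.0018,
16.2,,,,,,,,,,,,0.0218,,,,,,,,,
17,0.0909,0.3545,0.1655,0.0127,0.0036,0.0273,,0.0291,,,,0.0018,,,,,,,,,0.2873
17.2,,,,,,,,,,,,0.0018,,,,,,,,,
18,0.0327,0.0927,0.0218,0.0018,,0.0036,,,,,,,,,,,,,,,0.2327
19,0.0018,0.0109,0.0036,,,,,,,,,,,,,,,,,,0.0018
20,,0.0036,,,,,,,,,,,,,,,,,,,0.0491
23,,,,,,,,,,,,,,,,,,,,,0.0200
24,,,,,,,,,,,,,,,,,,,,,0.0018
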
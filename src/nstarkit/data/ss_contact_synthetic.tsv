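# nstarkit side-chain contact-energy table v1 (SYNTHETIC stand-in)
# symmetric pair well depths (kcal/mol) constructed from the Kyte-Doolittle
# hydropathy scale: eps_ab = 0.05 + 0.35*sqrt(h_a h_b), h normalised to [0,1];
# a qualitative statistical contact potential, not a calibrated one
# sha256: 58228cedf0b61da63dd4c20b7e8fc0eb411102afbe7bdc3fc9a487c16e3dd290
res A C D E F G H I K L M N P Q R S T V W Y
A 0.2950 0.3083 0.1476 0.1476 0.3137 0.2476 0.1613 0.3428 0.1256 0.3312 0.2969 0.1476 0.2162 0.1476 0.0500 0.2378 0.2403 0.3379 0.2352 0.2246
C 0.3083 0.3222 0.1529 0.1529 0.3280 0.2583 0.1673 0.3587 0.1297 0.3464 0.3103 0.1529 0.2252 0.1529 0.0500 0.2479 0.2506 0.3535 0.2452 0.2341
D 0.1476 0.1529 0.0889 0.0889 0.1551 0.1287 0.0943 0.1667 0.0801 0.1620 0.1484 0.0889 0.1162 0.0889 0.0500 0.1248 0.1258 0.1647 0.1238 0.1196
E 0.1476 0.1529 0.0889 0.0889 0.1551 0.1287 0.0943 0.1667 0.0801 0.1620 0.1484 0.0889 0.1162 0.0889 0.0500 0.1248 0.1258 0.1647 0.1238 0.1196
F 0.3137 0.3280 0.1551 0.1551 0.3339 0.2628 0.1698 0.3652 0.1314 0.3527 0.3158 0.1551 0.2289 0.1551 0.0500 0.2521 0.2548 0.3599 0.2494 0.2380
G 0.2476 0.2583 0.1287 0.1287 0.2628 0.2094 0.1398 0.2862 0.1110 0.2769 0.2492 0.1287 0.1841 0.1287 0.0500 0.2015 0.2035 0.2823 0.1994 0.1909
H 0.1613 0.1673 0.0943 0.0943 0.1698 0.1398 0.1006 0.1830 0.0843 0.1777 0.1622 0.0943 0.1255 0.0943 0.0500 0.1353 0.1364 0.1808 0.1341 0.1293
I 0.3428 0.3587 0.1667 0.1667 0.3652 0.2862 0.1830 0.4000 0.1404 0.3861 0.3451 0.1667 0.2487 0.1667 0.0500 0.2744 0.2774 0.3941 0.2714 0.2587
K 0.1256 0.1297 0.0801 0.0801 0.1314 0.1110 0.0843 0.1404 0.0733 0.1368 0.1262 0.0801 0.1013 0.0801 0.0500 0.1079 0.1087 0.1389 0.1072 0.1039
L 0.3312 0.3464 0.1620 0.1620 0.3527 0.2769 0.1777 0.3861 0.1368 0.3728 0.3334 0.1620 0.2408 0.1620 0.0500 0.2655 0.2684 0.3805 0.2626 0.2504
M 0.2969 0.3103 0.1484 0.1484 0.3158 0.2492 0.1622 0.3451 0.1262 0.3334 0.2989 0.1484 0.2175 0.1484 0.0500 0.2392 0.2418 0.3402 0.2367 0.2260
N 0.1476 0.1529 0.0889 0.0889 0.1551 0.1287 0.0943 0.1667 0.0801 0.1620 0.1484 0.0889 0.1162 0.0889 0.0500 0.1248 0.1258 0.1647 0.1238 0.1196
P 0.2162 0.2252 0.1162 0.1162 0.2289 0.1841 0.1255 0.2487 0.1013 0.2408 0.2175 0.1162 0.1628 0.1162 0.0500 0.1774 0.1791 0.2453 0.1757 0.1685
Q 0.1476 0.1529 0.0889 0.0889 0.1551 0.1287 0.0943 0.1667 0.0801 0.1620 0.1484 0.0889 0.1162 0.0889 0.0500 0.1248 0.1258 0.1647 0.1238 0.1196
R 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500 0.0500
S 0.2378 0.2479 0.1248 0.1248 0.2521 0.2015 0.1353 0.2744 0.1079 0.2655 0.2392 0.1248 0.1774 0.1248 0.0500 0.1939 0.1958 0.2706 0.1919 0.1838
T 0.2403 0.2506 0.1258 0.1258 0.2548 0.2035 0.1364 0.2774 0.1087 0.2684 0.2418 0.1258 0.1791 0.1258 0.0500 0.1958 0.1978 0.2736 0.1938 0.1856
V 0.3379 0.3535 0.1647 0.1647 0.3599 0.2823 0.1808 0.3941 0.1389 0.3805 0.3402 0.1647 0.2453 0.1647 0.0500 0.2706 0.2736 0.3883 0.2676 0.2552
W 0.2352 0.2452 0.1238 0.1238 0.2494 0.1994 0.1341 0.2714 0.1072 0.2626 0.2367 0.1238 0.1757 0.1238 0.0500 0.1919 0.1938 0.2676 0.1900 0.1820
Y 0.2246 0.2341 0.1196 0.1196 0.2380 0.1909 0.1293 0.2587 0.1039 0.2504 0.2260 0.1196 0.1685 0.1196 0.0500 0.1838 0.1856 0.2552 0.1820 0.1744
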
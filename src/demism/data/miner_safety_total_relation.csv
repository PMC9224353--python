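,x1,x2,x3,x4,x5,x6,x7,x8,x9,x10,x11,x12,x13,x14,x15,x16,x17,x18,x19,x20
x1,0.0984,0.1600,0.1074,0.1573,0.1670,0.0810,0.0730,0.1378,0.1425,0.0973,0.0936,0.1074,0.1042,0.1343,0.1649,0.0936,0.0970,0.1730,0.0694,0.1547
x2,0.1679,0.1333,0.1224,0.1784,0.1952,0.0915,0.0850,0.1692,0.1915,0.1443,0.1303,0.1601,0.1563,0.1705,0.1885,0.1334,0.1193,0.2008,0.0866,0.1807
x3,0.1232,0.1091,0.0569,0.1271,0.1359,0.0633,0.0593,0.1046,0.1310,0.0827,0.0723,0.0827,0.0768,0.1025,0.1244,0.0691,0.0721,0.1207,0.0568,0.1230
x4,0.1195,0.1202,0.0686,0.0817,0.1160,0.0541,0.0532,0.1092,0.1049,0.0661,0.0696,0.0925,0.0674,0.1016,0.1256,0.0612,0.0667,0.1225,0.0513,0.1273
x5,0.1164,0.1441,0.0786,0.1467,0.1010,0.0678,0.0694,0.1435,0.1329,0.0780,0.0980,0.0972,0.0844,0.1223,0.1332,0.0748,0.0876,0.1476,0.0632,0.1360
x6,0.1358,0.1739,0.1026,0.1818,0.1829,0.0864,0.1098,0.1891,0.1870,0.1442,0.1158,0.1565,0.1653,0.1552,0.1793,0.1119,0.1230,0.1891,0.0951,0.1660
x7,0.1340,0.1722,0.0910,0.1765,0.1805,0.1247,0.0786,0.1842,0.1818,0.1488,0.1144,0.1489,0.1610,0.1502,0.1866,0.1066,0.1184,0.1811,0.0978,0.1668
x8,0.1689,0.1905,0.1194,0.1980,0.2121,0.1363,0.1281,0.1528,0.2025,0.1391,0.1499,0.1789,0.1698,0.1922,0.2154,0.1397,0.1389,0.2131,0.1311,0.1962
x9,0.1738,0.1889,0.1339,0.2035,0.2115,0.1405,0.1262,0.2103,0.1561,0.1687,0.1536,0.1774,0.1772,0.1882,0.2148,0.1403,0.1464,0.2030,0.1177,0.1986
x10,0.1604,0.1639,0.1138,0.1812,0.1765,0.1184,0.1111,0.1886,0.1953,0.1054,0.1307,0.1672,0.1616,0.1738,0.1984,0.1239,0.1385,0.1803,0.1124,0.1773
x11,0.2045,0.2299,0.1588,0.2366,0.2459,0.1813,0.1688,0.2464,0.2384,0.1790,0.1374,0.2181,0.2182,0.2336,0.2559,0.1789,0.1895,0.2582,0.1445,0.2263
x12,0.2035,0.2176,0.1483,0.2215,0.2395,0.1562,0.1413,0.2310,0.2289,0.1870,0.1772,0.1546,0.2067,0.2254,0.2463,0.1816,0.1891,0.2394,0.1308,0.2240
x13,0.2006,0.2334,0.1670,0.2437,0.2499,0.1724,0.1545,0.2505,0.2456,0.1958,0.1755,0.2157,0.1574,0.2347,0.2567,0.1798,0.1903,0.2440,0.1344,0.2159
x14,0.1786,0.2135,0.1404,0.2113,0.2260,0.1499,0.1448,0.2306,0.2252,0.1737,0.1698,0.1954,0.1929,0.1580,0.2297,0.1713,0.1751,0.2289,0.1221,0.1937
x15,0.1919,0.2067,0.1348,0.2003,0.2086,0.1275,0.1227,0.1975,0.1952,0.1499,0.1591,0.1702,0.1796,0.1879,0.1656,0.1554,0.1552,0.2180,0.1191,0.1775
x16,0.1567,0.1699,0.1558,0.1970,0.2016,0.1249,0.1239,0.1938,0.1832,0.1426,0.1368,0.1526,0.1617,0.1783,0.2072,0.1013,0.1537,0.1891,0.1109,0.1831
x17,0.1430,0.1580,0.1405,0.1813,0.1855,0.1196,0.1068,0.1697,0.1741,0.1399,0.1279,0.1485,0.1546,0.1606,0.1910,0.1109,0.0984,0.1703,0.1009,0.1678
x18,0.1958,0.2164,0.1583,0.2225,0.2224,0.1273,0.1226,0.2031,0.2115,0.1544,0.1571,0.1963,0.1805,0.1938,0.2335,0.1535,0.1624,0.1697,0.0940,0.2080
x19,0.2208,0.2399,0.1500,0.2346,0.2378,0.1817,0.1623,0.2382,0.2363,0.1857,0.2023,0.2465,0.2228,0.2382,0.2669,0.1921,0.2029,0.2600,0.1071,0.2306
x20,0.2033,0.2082,0.1485,0.2104,0.2188,0.1302,0.1039,0.1820,0.1990,0.1370,0.1566,0.1796,0.1667,0.1886,0.2126,0.1499,0.1589,0.2134,0.1313,0.1507
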
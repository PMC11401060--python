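H MEIH800101
D Average reduced distance for C-alpha (Meirovitch et al., 1980)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.93    0.98    0.98    1.01    0.88    1.02    1.02    1.01    0.89    0.79
    0.85    1.05    0.84    0.78    1.00    1.02    0.99    0.83    0.93    0.81
//
H VASM830102
D Relative population of conformational state C (Vasquez et al., 1983)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.507   0.459   0.287   0.223   0.592   0.383   0.445   0.390   0.310   0.111
   0.619   0.559   0.431   0.077   0.739   0.689   0.785   0.160   0.060   0.356
//
H CHAM830107
D A parameter of charge transfer capability (Charton-Charton, 1983)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
       0       0       1       1       0       0       1       1       0       0
       0       0       0       0       0       0       0       0       0       0
//
H KLEP840101
D Net charge (Klein et al., 1984)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
       0       1       0      -1       0       0      -1       0       0       0
       0       1       0       0       0       0       0       0       0       0
//
H FAUJ880112
D Negative charge (Fauchere et al., 1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
       0       0       0       1       0       0       1       0       0       0
       0       0       0       0       0       0       0       0       0       0
//
H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
     3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7    -0.9    -1.3     4.2
//
H ZIMJ680104
D Isoelectric point (Zimmerman et al., 1968)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    6.00   10.76    5.41    2.77    5.05    5.65    3.22    5.97    7.59    6.02
    5.98    9.74    5.74    5.48    6.30    5.68    5.66    5.89    5.66    5.96
//
H FAUJ880103
D Normalized van der Waals volume (Fauchere et al., 1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.00    6.13    2.95    2.78    2.43    3.95    3.78    0.00    4.66    4.00
    4.00    4.77    4.43    5.89    2.72    1.60    2.60    8.08    6.47    3.00
//
H GRAR740102
D Polarity (Grantham, 1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     8.1    10.5    11.6    13.0     5.5    10.5    12.3     9.0    10.4     5.2
     4.9    11.3     5.7     5.2     8.0     9.2     8.6     5.4     6.2     5.9
//
H HOPT810101
D Hydrophilicity value (Hopp-Woods, 1981)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    -0.5     3.0     0.2     3.0    -1.0     0.2     3.0     0.0    -0.5    -1.8
    -1.8     3.0    -1.3    -2.5     0.0     0.3    -0.4    -3.4    -2.3    -1.5
//
H JANJ780101
D Average accessible surface area (Janin et al., 1978)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    27.8    94.7    60.1    60.6    15.5    68.7    68.2    24.5    50.7    22.8
    27.6   103.0    33.5    25.5    51.5    42.0    45.0    34.7    55.2    23.7
//
H CHOC760101
D Residue accessible surface area in tripeptide (Chothia, 1976)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     115     225     160     150     135     180     190      75     195     175
     170     200     185     210     145     115     140     255     230     155
//
H BIGC670101
D Residue volume (Bigelow, 1967)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    52.6   109.1    75.7    68.4    68.3    89.7    84.7    36.3    91.9   102.0
   102.0   105.1    97.7   113.9    73.6    54.9    71.2   135.4   116.2    85.1
//
H FASG760101
D Molecular weight (Fasman, 1976)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   89.09  174.20  132.12  133.10  121.15  146.15  147.13   75.07  155.16  131.17
  131.17  146.19  149.21  165.19  115.13  105.09  119.12  204.24  181.19  117.15
//
H EISD840101
D Consensus normalized hydrophobicity scale (Eisenberg, 1984)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.25   -1.76   -0.64   -0.72    0.04   -0.69   -0.62    0.16   -0.40    0.73
    0.53   -1.10    0.26    0.61   -0.07   -0.26   -0.18    0.37    0.02    0.54
//
H FAUJ880111
D Positive charge (Fauchere et al., 1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
       0       1       0       0       0       0       0       0       1       0
       0       1       0       0       0       0       0       0       0       0
//
H RADA880108
D Mean polarity (Radzicka-Wolfenden, 1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -0.06   -0.84   -0.48   -0.80    1.36   -0.73   -0.77   -0.41    0.49    1.31
    1.21   -1.18    1.27    1.27    0.00   -0.50   -0.27    0.88    0.33    1.09
//
H WOLS870101
D Principal property value z1 (Wold et al., 1987)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.07    2.88    3.22    3.64    0.71    2.18    3.08    2.23    2.41   -4.44
   -4.19    2.84   -2.49   -4.92   -1.22    1.96    0.92   -4.75   -1.39   -2.69
//
H ZIMJ680102
D Bulkiness (Zimmerman et al., 1968)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   11.50   14.28   12.82   11.68   13.46   14.45   13.57    3.40   13.69   21.40
   21.40   15.71   16.25   19.80   17.43    9.47   15.77   21.67   18.03   21.57
//
H CHAM820101
D Polarizability parameter (Charton-Charton, 1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.046   0.291   0.134   0.105   0.128   0.180   0.151   0.000   0.230   0.186
   0.186   0.219   0.221   0.290   0.131   0.062   0.108   0.409   0.298   0.140
//
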
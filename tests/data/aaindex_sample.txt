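H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
     3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7     4.2    -0.9    -1.3
//
H FASG760101
D Molecular weight
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    89.1   174.2   132.1   133.1   121.2   146.2   147.1    75.1   155.2   131.2
   131.2   146.2   149.2   165.2   115.1   105.1   119.1   117.1   204.2   181.2
//
H SYNT000001
D Synthetic incomplete scale used to exercise NA filtering
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.0     2.0      NA     4.0     5.0     6.0     7.0     8.0     9.0    10.0
    11.0    12.0    13.0    14.0    15.0    16.0    17.0    18.0    19.0    20.0
//
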
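Query         target
Match_columns 40
No_of_seqs    12 out of 57
Neff          4.8
Searched_HMMs 120
Date          Mon Jan  6 12:00:00 2020
Command       hhsearch -i target.a3m -d pdb70

 No Hit                             Prob E-value P-value  Score    SS Cols Query HMM  Template HMM
  1 tmplA example protein one       99.8 1.2E-30 1.0E-34  210.5  12.3   40    1-40      1-40  (40)
  2 tmplB example protein two       85.3 2.2E-10 2.0E-14   95.2   8.1   35    3-37      5-39  (45)

No 1
>tmplA example protein one
Probab=99.80  E-value=1.2e-30  Score=210.50  Aligned_cols=40  Identities=80%  Similarity=1.2  Sum_probs=38.0

Q target            1 AVLDFKSTIEMGNQRWAVLDFKSTIEMGNQRWAVLDFKST   40 (40)
Q Consensus         1 avldfkstiemgnqrwavldfkstiemgnqrwavldfkst   40 (40)
T Consensus         1 avldfkstiemgnqrwavldfkstiemgnqrwavldfkst   40 (40)
T tmplA             1 AVLDFKSTIEMGNQRWAVLDFKSTIEMGNQRWAVLDFKST   40 (40)
Confidence            9999999999999999999999999999999999999999

No 2
>tmplB example protein two
Probab=85.30  E-value=2.2e-10  Score=95.20  Aligned_cols=35  Identities=40%  Similarity=0.6  Sum_probs=30.1

Q target            3 LDFKSTIEMGNQRWAVLDFKSTIEMGNQRWAVLDF   37 (40)
Q Consensus         3 ldfkstiemgnqrwavldfkstiemgnqrwavldf   37 (40)
T Consensus         5 ldfkstiemgnqrwavldfkstiemgnqrwavldf   39 (45)
T tmplB             5 LDFKSTIEMGNQRWAVLDFKSTIEMGNQRWAVLDF   39 (45)
Confidence            99999999999999999999999999999999999
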
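// Root stem-cell-niche model with the fas mutant: every row of the SCR
// table is indeterminate, modeling deregulated SCR expression.

target ARF : IAA;
0 : 1
1 : 0

target AUXINS : AUXINS;
0 : 0
1 : 1

target IAA : AUXINS;
0 : 1
1 : 0

target JKD : SCR SHR;
0 0 : 0
0 1 : 0
1 0 : 0
1 1 : 1

target MGP : SCR SHR WOX;
0 0 0 : 0
0 0 1 : 0
0 1 0 : 0
0 1 1 : 0
1 0 0 : 0
1 0 1 : 0
1 1 0 : 1
1 1 1 : 0

target PLT : ARF;
0 : 0
1 : 1

target SCR : SHR SCR JKD MGP;
0 0 0 0 : *
0 0 0 1 : *
0 0 1 0 : *
0 0 1 1 : *
0 1 0 0 : *
0 1 0 1 : *
0 1 1 0 : *
0 1 1 1 : *
1 0 0 0 : *
1 0 0 1 : *
1 0 1 0 : *
1 0 1 1 : *
1 1 0 0 : *
1 1 0 1 : *
1 1 1 0 : *
1 1 1 1 : *

target SHR : SHR;
0 : 0
1 : 1

target WOX : ARF MGP SCR SHR WOX;
0 0 0 0 0 : 0
0 0 0 0 1 : 0
0 0 0 1 0 : 0
0 0 0 1 1 : 0
0 0 1 0 0 : 0
0 0 1 0 1 : 0
0 0 1 1 0 : 0
0 0 1 1 1 : 0
0 1 0 0 0 : 0
0 1 0 0 1 : 0
0 1 0 1 0 : 0
0 1 0 1 1 : 0
0 1 1 0 0 : 0
0 1 1 0 1 : 0
0 1 1 1 0 : 0
0 1 1 1 1 : 0
1 0 0 0 0 : 0
1 0 0 0 1 : 0
1 0 0 1 0 : 0
1 0 0 1 1 : 0
1 0 1 0 0 : 0
1 0 1 0 1 : 0
1 0 1 1 0 : 1
1 0 1 1 1 : 1
1 1 0 0 0 : 0
1 1 0 0 1 : 0
1 1 0 1 0 : 0
1 1 0 1 1 : 0
1 1 1 0 0 : 0
1 1 1 0 1 : 0
1 1 1 1 0 : 0
1 1 1 1 1 : 1
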
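residue_number,residue,aln_column,entropy_score,entropy_top_fraction,discriminant_score,discriminant_top_fraction,determinant_score,determinant_top_fraction,discriminant_g1_score,discriminant_g2_score,accessibility,structure_residue,notes
1,N,1,2.2739657164192466,0.55,0.1875,0.5666666666666667,0.1875,0.4,0.1875,0.1875,,1,
2,V,2,2.220025327834538,0.4666666666666667,0.15625,0.8,0.15625,0.6666666666666666,0.15625,0.15625,,2,
3,S,3,1.981332514723983,0.2,0.125,0.9333333333333333,0.125,0.8,0.125,0.125,,3,
4,F,4,2.0467385326945515,0.26666666666666666,0.28125,0.18333333333333332,0.28125,0.1,0.28125,0.28125,,4,
5,G,5,0.0,0.03333333333333333,0.0,1.0,0.0,1.0,0.0,0.0,,5,
6,T,6,2.3933121229745242,0.7833333333333333,0.1875,0.5666666666666667,0.1875,0.4,0.1875,0.1875,,6,
7,A,7,2.1333819302645445,0.36666666666666664,0.28125,0.18333333333333332,0.1875,0.4,0.28125,0.1875,,7,
8,S,8,1.6886993130287196,0.13333333333333333,0.140625,0.9,0.140625,0.7666666666666667,0.140625,0.140625,,8,
9,S,9,2.306668725404531,0.6333333333333333,0.15625,0.8,0.15625,0.6666666666666666,0.15625,0.15625,,9,
10,K,10,2.4260151319598084,0.9166666666666666,0.1875,0.5666666666666667,0.1875,0.4,0.1875,0.1875,,10,
11,G,11,2.252728336819822,0.5,0.15625,0.8,0.15625,0.6666666666666666,0.15625,0.15625,,11,
12,G,12,2.067975912293976,0.3,0.15625,0.8,0.15625,0.6666666666666666,0.15625,0.15625,,12,
13,G,13,2.0963525794641384,0.3333333333333333,0.234375,0.2833333333333333,0.15625,0.6666666666666666,0.15625,0.234375,,13,
14,K,14,2.3393717343898155,0.7,0.28125,0.18333333333333332,0.09375,0.8833333333333333,0.09375,0.28125,,14,
15,D,15,0.6931471805599453,0.06666666666666667,1.0,0.05,1.0,0.03333333333333333,1.0,1.0,,15,
16,L,16,2.393312122974524,0.7333333333333333,0.1875,0.5666666666666667,0.1875,0.4,0.1875,0.1875,,16,
17,Y,17,2.306668725404531,0.6333333333333333,0.1875,0.5666666666666667,0.1875,0.4,0.1875,0.1875,,17,
18,S,18,1.9600951351245584,0.16666666666666666,0.09375,0.9666666666666667,0.09375,0.8833333333333333,0.09375,0.09375,,18,
19,N,19,2.0140355237092673,0.23333333333333334,0.1875,0.5666666666666667,0.1875,0.4,0.1875,0.1875,,19,
20,Y,20,2.3933121229745242,0.7833333333333333,0.1875,0.5666666666666667,0.1875,0.4,0.1875,0.1875,,20,
21,F,21,2.5126585295298014,0.9666666666666667,0.21875,0.36666666666666664,0.21875,0.18333333333333332,0.21875,0.21875,,21,
22,E,22,2.426015131959808,0.85,0.1875,0.5666666666666667,0.1875,0.4,0.1875,0.1875,,22,
23,N,23,2.306668725404531,0.6333333333333333,0.234375,0.2833333333333333,0.078125,0.95,0.234375,0.078125,,23,
24,A,24,2.1873223188492537,0.4166666666666667,0.28125,0.18333333333333332,0.1875,0.4,0.28125,0.1875,,24,
25,R,25,1.6462245538298699,0.1,1.0,0.05,0.25,0.13333333333333333,1.0,0.25,,25,
26,L,26,2.4260151319598084,0.9166666666666666,0.21875,0.36666666666666664,0.21875,0.18333333333333332,0.21875,0.21875,,26,
27,K,27,2.1873223188492537,0.4166666666666667,0.328125,0.1,0.328125,0.06666666666666667,0.328125,0.328125,,27,
28,V,28,2.599301927099795,1.0,0.21875,0.36666666666666664,0.109375,0.8333333333333334,0.21875,0.109375,,28,
29,N,29,2.2739657164192466,0.55,0.15625,0.8,0.078125,0.95,0.15625,0.078125,,29,
30,L,30,2.426015131959808,0.85,0.1875,0.5666666666666667,0.1875,0.4,0.1875,0.1875,,30,
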
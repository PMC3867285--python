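residue_number,residue,aln_column,entropy_score,entropy_top_fraction,rvet_score,rvet_top_fraction,accessibility,structure_residue,notes
1,N,1,1.9061547465398496,0.8,5.005388322826314,0.5833333333333334,,,
2,V,2,1.7328679513998633,0.5,4.855206433704994,0.36666666666666664,,,
3,S,3,1.7328679513998633,0.5,4.862908069044548,0.4,,,
4,F,4,1.6674619334292946,0.2833333333333333,4.195348268174939,0.16666666666666666,,,
5,G,5,0.0,0.06666666666666667,1.0,0.06666666666666667,,,
6,T,6,1.9061547465398496,0.8,5.2738453260908,0.8,,,
7,A,7,1.4941751382893085,0.18333333333333332,4.379996467974193,0.2,,,
8,S,8,1.3208883431493221,0.13333333333333333,3.906125827079905,0.13333333333333333,,,
9,S,9,1.9061547465398496,0.8,5.2738453260908,0.8,,,
10,K,10,1.9061547465398496,0.8,5.2738453260908,0.8,,,
11,G,11,1.7328679513998633,0.5,5.246889602402359,0.7,,,
12,G,12,1.559581156259877,0.23333333333333334,4.482777353356515,0.26666666666666666,,,
13,G,13,1.7328679513998633,0.5,4.961929094838825,0.5,,,
14,K,14,2.0794415416798357,1.0,5.692484218476609,1.0,,,
15,D,15,0.0,0.06666666666666667,1.0,0.06666666666666667,,,
16,L,16,1.9061547465398496,0.8,5.2738453260908,0.8,,,
17,Y,17,1.7328679513998633,0.5,5.001537505156537,0.5333333333333333,,,
18,S,18,1.7328679513998633,0.5,4.924521151760988,0.4666666666666667,,,
19,N,19,1.6674619334292948,0.35,4.792670925058413,0.3333333333333333,,,
20,Y,20,1.9061547465398496,0.8,5.104409348620592,0.6666666666666666,,,
21,F,21,1.9061547465398496,0.8,5.005388322826314,0.5833333333333334,,,
22,E,22,1.9061547465398496,0.8,5.2738453260908,0.8,,,
23,N,23,1.6674619334292948,0.35,4.898756619774216,0.43333333333333335,,,
24,A,24,1.4941751382893085,0.18333333333333332,4.385277568562215,0.23333333333333334,,,
25,R,25,0.0,0.06666666666666667,1.0,0.06666666666666667,,,
26,L,26,1.9061547465398496,0.8,5.519197423336623,0.95,,,
27,K,27,1.6674619334292946,0.2833333333333333,4.623234947588204,0.3,,,
28,V,28,1.9061547465398496,0.8,5.343160044146795,0.9,,,
29,N,29,1.7328679513998633,0.5,5.100558530950814,0.6333333333333333,,,
30,L,30,1.9061547465398496,0.8,5.519197423336623,0.95,,,
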
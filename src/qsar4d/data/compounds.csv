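id,R,Rprime,role,pic50_exp
1,6-OH,4'-OH,train,9.70
2,6-OH,"3'-F, 4'-OH",train,9.52
3,6-OH,2'-Me,train,9.15
4,6-OH,4'-C#CH,train,9.10
5,6-OH,"3'-Me, 4'-OH",train,9.00
6,6-OH,4'-Cl,train,9.00
7,6-OH,"2'-Me, 4'-OH",train,8.70
8,6-OH,"2'-OMe, 4'-OH",test,8.70
9,6-OH,"3'-Cl, 4'-OH",train,8.64
10,6-OH,4'-F,train,8.64
11,6-OH,H,train,8.60
12,6-OH,3'-F,train,8.60
13,"5-F, 6-OH",4'-OH,train,8.52
14,6-OH,4'-Et,test,8.30
15,6-OH,4'-CH=CH2,train,8.15
16,6-OH,2'-OH,train,8.00
17,6-OH,4'-nBu,test,8.00
18,6-OH,4'-CONMe2,test,7.70
19,6-C#CH,4'-OH,train,7.70
20,6-OH,4'-iPr,test,7.52
21,6-CO2Me,4'-OH,train,7.52
22,6-OH,4'-COMe,train,7.49
23,H,4'-OH,train,7.46
24,6-OH,4'-CONHMe,train,7.40
25,6-OH,4'-Me,train,7.30
26,6-OH,4'-CO2Me,test,7.30
27,6-OH,4'-CO2Et,train,7.30
28,6-COMe,4'-OH,train,7.22
29,"4,7-di(Me), 6-OH",4'-OH,train,7.00
30,H,4'-OMe,train,7.00
31,5-OH,4'-OH,test,7.00
32,6-OH,4'-Ph,train,7.00
33,6-OH,4'-CH2SEt,test,7.00
34,6-OH,"3',5'-di(Me), 4'-OH",train,7.00
35,4-OH,4'-OH,train,6.72
36,6-OH,4'-CONH2,train,6.70
37,6-OMe,4'-OH,train,6.60
38,H,H,train,6.52
39,6-OMe,4'-OMe,train,6.52
40,6-Me,4'-OH,test,6.52
41,7-OH,4'-OH,test,6.52
42,6-OH,4'-CO2H,train,6.49
43,"5,6,7-tri(OMe)",4'-OMe,train,6.46
44,"4,6-di(OH)",4'-OH,train,6.46
45,"5,6-di(OH)",4'-OH,train,6.40
46,6-OH,4'-NO2,test,6.30
47,"4,5-benzo, 6-OH",4'-OH,train,6.30
48,6-OMe,"3',4'-OCH2O-",test,6.30
49,"5,7-di(Me), 6-OH",4'-OH,train,6.30
50,6-OMe,4'-CH2OH,train,6.22
51,6-OH,4'-OMe,test,6.00
52,6-CONH2,4'-OH,train,6.00
53,6-Cl,4'-OH,train,6.00
54,6-OH,4'-CF3,train,6.00
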
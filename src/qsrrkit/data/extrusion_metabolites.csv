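no,metabolite,before_mean,after_mean,log2fc_printed,label,p_adj,vip
1,erythritol,0.0396,0.0214,-0.89,Decrease,1.78e-02,1.09
2,"2,3-butanediol",0.2532,0.1340,-0.92,No change,>0.05,<1.00
3,glycerol,0.9457,0.5934,-0.67,No change,>0.05,<1.00
4,arabitol,0.0130,0.0071,-0.86,No change,>0.05,<1.00
5,diglycerol,0.0169,0.0054,-1.64,No change,>0.05,<1.00
6,ethanolamine,0.0007,0.0391,5.90,Increase,2.97e-04,1.37
7,glycine,0.0023,0.0165,2.82,Increase,5.83e-04,1.33
8,cycloleucine,0.0193,0.0087,-1.15,Decrease,1.91e-02,1.09
9,glutamic acid,3.1486,0.9798,-1.69,Decrease,6.02e-05,1.41
10,glucosamine-phosphate,0.0168,0.0065,-1.40,Decrease,2.26e-03,1.29
11,galactosamine,0.0331,0.0023,-3.84,Decrease,3.06e-04,1.34
12,tyramine,0.0023,0.0678,4.89,Increase,2.70e-03,1.27
13,glucosaminic acid,11.9755,1.3405,-3.18,Decrease,1.06e-02,1.15
14,valine,0.0434,0.0279,-0.64,No change,>0.05,<1.00
15,valeramide,0.2337,0.1664,-0.49,No change,>0.05,<1.00
16,isoleucine,0.0129,0.0062,-1.06,No change,>0.05,<1.00
17,serine,0.0172,0.0143,-0.27,No change,>0.05,<1.00
18,pipecolic acid,0.0060,0.0066,0.14,No change,>0.05,<1.00
19,threonine,0.0051,0.0030,-0.79,No change,>0.05,<1.00
20,malonamide,0.0015,0.0022,0.56,No change,>0.05,<1.00
21,acetyl-glutamic acid,0.0891,0.0284,-1.64,No change,>0.05,<1.00
22,ornithine,0.0357,0.0249,-0.51,No change,>0.05,<1.00
23,2-deoxy-ribose,0.0323,0.0134,-1.25,Decrease,7.73e-03,1.17
24,deoxyglucose,0.0148,0.0046,-1.69,Decrease,1.04e-03,1.33
25,"1,5-anhydroglucitol",0.0073,0.0078,0.08,Increase,2.71e-02,1.04
26,methyl-galactopyranoside,4.2884,0.0147,0,Decrease,4.92e-03,1.21
27,galactonic acid,0.1845,0.0116,-4.06,Decrease,1.37e-03,1.30
28,sorbose,0.2021,0.0091,-4.64,Decrease,7.67e-03,1.18
29,galactose,0.2058,0.0114,-4.06,Decrease,1.24e-02,1.12
30,mannose,0.0380,0.0033,-3.47,Decrease,1.24e-05,1.42
31,sedoheptulose anhydride monohydrate,11.1883,0.2812,-5.06,Decrease,6.72e-04,1.33
32,glucose,65.2808,27.9535,-1.22,Decrease,1.52e-02,1.10
33,glucoheptonic acid,3.8824,1.5047,-1.36,Decrease,6.37e-05,1.41
34,mucic acid,0.7020,0.1846,-1.94,Decrease,5.81e-03,1.20
35,"1,5-anhydrosorbitol",2.0258,0.0109,-6.64,No change,>0.05,<1.00
36,xylose,0.0192,0.0113,-0.76,No change,>0.05,<1.00
37,ribose,0.0080,0.0028,-1.51,No change,>0.05,<1.00
38,fructose,53.5614,27.4699,-0.97,No change,>0.05,<1.00
39,palmitic acid,0.7225,0.4756,-0.60,Decrease,2.81e-02,1.04
40,nonanoic acid,0.0044,0.0026,-0.76,No change,>0.05,<1.00
41,heptadecanoic acid,0.0022,0.0016,-0.47,No change,>0.05,<1.00
42,2-furoic acid,0.0013,0.0034,1.42,Increase,2.23e-03,1.28
43,malonic acid,0.0808,0.0365,-1.15,Decrease,3.86e-02,<1.00
44,fumaric acid,0.0870,0.0292,-1.56,Decrease,2.47e-02,1.05
45,hydroxyhexanoic acid,0.1176,0.0369,-1.69,Decrease,1.31e-03,1.30
46,malic acid,1.3460,0.4315,-1.64,Decrease,2.72e-04,1.37
47,hydroxyglutaric acid,0.0064,0.0018,-1.84,Decrease,3.00e-03,1.24
48,aconitic acid,0.0026,0.0012,-1.18,Decrease,3.17e-04,1.35
49,dihydroxybenzoic acid,0.0857,0.0272,-1.64,Decrease,3.95e-05,1.42
50,quinic acid,12.0297,2.7977,-2.12,Decrease,7.00e-05,1.40
51,gluconic acid lactone,0.1219,0.0498,-1.29,Decrease,3.37e-02,1.01
52,glucuronolactone,83.1777,38.6568,-1.12,Decrease,3.90e-02,<1.00
53,gallic acid,0.0172,0.0046,-1.94,Decrease,3.43e-07,1.47
54,shikimic acid,1.0267,0.1383,-2.94,Decrease,3.38e-05,1.41
55,pyruvic acid,0.0139,0.0118,-0.23,No change,>0.05,<1.00
56,lactic acid,1.0819,0.7853,-0.45,No change,>0.05,<1.00
57,glycolic acid,0.0267,0.0226,-0.23,No change,>0.05,<1.00
58,oxalic acid,2.2650,1.4398,-0.64,No change,>0.05,<1.00
59,hydroxybutyric acid,0.0017,0.0013,-0.34,No change,>0.05,<1.00
60,nicotinic acid,0.0049,0.0020,-1.32,No change,>0.05,<1.00
61,succinic acid,0.7125,0.3913,-0.86,No change,>0.05,<1.00
62,glyceric acid,0.0630,0.0325,-0.94,No change,>0.05,<1.00
63,dihydroxymalonic acid,0.0024,0.0025,0.08,No change,>0.05,<1.00
64,3-hydroxypropanoic acid,0.0099,0.0055,-0.84,No change,>0.05,<1.00
65,hydroxybenzoic acid,0.0027,0.0026,0.00,No change,>0.05,<1.00
66,vanillic acid,0.0019,0.0021,0.19,No change,>0.05,<1.00
67,gulonic acid lactone,6.9292,1.4171,-2.32,No change,>0.05,<1.00
68,caffeine,1.8938,1.0039,-0.92,Decrease,2.81e-03,1.26
69,"1,2-dihydro-1,2-naphthalenediol",0.0049,0.0048,-0.04,No change,>0.05,<1.00
70,4-O-methylphloracetophenone,0.0018,0.0020,0.14,No change,>0.05,<1.00
71,"1,3-dihydroxyacetone",0.0196,0.0116,-0.76,No change,>0.05,<1.00
72,phosphoric acid,2.6289,0.9594,-1.47,Decrease,2.88e-03,1.24
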
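value
0.1808583885431290
0.2715894281864170
0.1936905533075330
0.0500552132725716
0.1485721915960310
0.2600140273571010
0.1304957568645480
0.0394391231238842
0.1323543041944500
0.1426382064819340
0.1129530519247060
0.0269157197326422
0.1067145913839340
0.1392973661422730
0.1899524927139280
0.0408989638090134
0.0712180733680725
0.2190646529197690
0.2168500870466230
0.0581964328885078
0.0793552622199059
0.2000004947185520
0.1894772350788120
0.0580895692110062
0.1066346019506450
0.1789414286613460
0.3403762280941010
0.0606064833700657
0.1967413872480390
0.1636120975017550
0.3936370909214020
0.0446394421160221
0.2471709847450260
0.0708507150411606
0.2923302650451660
0.0352656245231628
0.1918695569038390
0.0410193651914597
0.2552164196968080
0.0405378639698029
0.2030045837163930
0.0735185071825981
0.2565241158008580
0.0408119037747383
0.1835628747940060
0.1043748185038570
0.2619580626487730
0.0332400277256966
0.1022637560963630
0.1391180157661440
0.1960394680500030
0.0511302277445793
0.0658624023199081
0.1735171675682070
0.1375353783369060
0.0748695135116577
0.0659949705004692
0.2414010912179950
0.0767071023583412
0.0701084062457085
0.0655298158526421
0.2916960418224330
0.0188371986150742
0.0451735183596611
0.0934262275695801
0.2644947469234470
0.0086520370095968
0.0497028753161430
0.1310033947229390
0.2680946886539460
0.0113833881914616
0.0558364242315292
0.1225134804844860
0.2704213559627530
0.0123042017221451
0.0474526733160019
0.1350584030151370
0.2464897632598880
0.0281006377190351
0.0475621223449707
0.1977708339691160
0.1754100024700160
0.0552334710955620
0.0600663721561432
0.2574170231819150
0.1352893263101580
0.0505803674459457
0.0659491419792175
0.2282601296901700
0.1485791504383090
0.0341098383069038
0.0429943427443504
0.2165334820747380
0.1938208043575290
0.0539951920509338
0.0441263243556023
0.2357383966445920
0.2253356277942660
0.0620105266571045
0.0437876060605049
0.0405787900090218
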
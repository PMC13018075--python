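age,sex,mu_ln,sd_ln
2.0,M,4.0943445622221,0.35
3.0,M,4.248495242049359,0.35
4.0,M,4.442651256490317,0.35
5.0,M,4.605170185988092,0.35
6.0,M,4.74493212836325,0.35
7.0,M,4.867534450455582,0.35
8.0,M,5.0106352940962555,0.35
9.0,M,5.135798437050262,0.35
10.0,M,5.247024072160486,0.35
11.0,M,5.3706380281276624,0.35
12.0,M,5.501258210544727,0.35
13.0,M,5.634789603169249,0.35
14.0,M,5.768320995793772,0.35
15.0,M,5.857933154483459,0.35
16.0,M,5.91350300563827,0.35
17.0,M,5.940171252720432,0.35
18.0,M,5.940171252720432,0.35
2.0,F,4.174387269895637,0.35
3.0,F,4.382026634673881,0.35
4.0,F,4.553876891600541,0.35
5.0,F,4.700480365792417,0.35
6.0,F,4.867534450455582,0.35
7.0,F,5.0106352940962555,0.35
8.0,F,5.135798437050262,0.35
9.0,F,5.272999558563747,0.35
10.0,F,5.41610040220442,0.35
11.0,F,5.560681631015528,0.35
12.0,F,5.703782474656201,0.35
13.0,F,5.8289456176102075,0.35
14.0,F,5.91350300563827,0.35
15.0,F,5.953243334287785,0.35
16.0,F,5.966146739123692,0.35
17.0,F,5.953243334287785,0.35
18.0,F,5.940171252720432,0.35
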
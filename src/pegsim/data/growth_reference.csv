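age,sex,weight_median,weight_sd_ln,height_median
2.0,M,12.5,0.13,88.5
3.0,M,14.7,0.13,96.8
4.0,M,16.7,0.13,104.1
5.0,M,18.9,0.13,111.3
6.0,M,21.3,0.13,117.7
7.0,M,24.1,0.13,124.0
8.0,M,27.3,0.13,130.0
9.0,M,30.5,0.13,135.4
10.0,M,33.8,0.13,140.2
11.0,M,37.5,0.13,145.3
12.0,M,41.6,0.13,151.9
13.0,M,46.5,0.13,159.5
14.0,M,51.6,0.13,165.9
15.0,M,56.0,0.13,169.8
16.0,M,59.3,0.13,171.6
17.0,M,61.5,0.13,172.3
18.0,M,63.0,0.13,172.7
2.0,F,11.9,0.13,87.2
3.0,F,14.1,0.13,95.6
4.0,F,16.2,0.13,103.1
5.0,F,18.3,0.13,110.2
6.0,F,20.6,0.13,116.6
7.0,F,23.3,0.13,122.5
8.0,F,26.4,0.13,128.5
9.0,F,29.9,0.13,134.1
10.0,F,33.9,0.13,140.1
11.0,F,38.2,0.13,146.6
12.0,F,42.5,0.13,152.4
13.0,F,46.3,0.13,156.3
14.0,F,49.4,0.13,158.6
15.0,F,51.6,0.13,159.8
16.0,F,53.0,0.13,160.1
17.0,F,53.8,0.13,160.3
18.0,F,54.2,0.13,160.6
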
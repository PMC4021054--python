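id,side,microct_bvtv_percent,mr_bvtv_percent
1,right,44.98,4.32
2,right,28.39,1.23
3,right,15.28,2.03
4,right,32.16,4.25
5,right,12.13,0.09
1,left,33.74,5.03
2,left,31.79,0.62
3,left,15.55,1.17
4,left,38.11,3.02
5,left,14.26,0.20
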
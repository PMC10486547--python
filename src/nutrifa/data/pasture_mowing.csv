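row_type,fa_label,before_mg,before_mg_sem,before_pct,before_pct_sem,after_mg,after_mg_sem,after_pct,after_pct_sem
fa,12:0,trace,,0.5,0.0,0.1,0.0,1.2,0.2
fa,14:0,trace,,0.8,0.2,0.1,0.1,2.7,0.1
fa,15:0,trace,,0.3,0.1,trace,,0.7,0.2
fa,16:0,2.4,0.0,22.5,1.4,1.8,0.7,34.1,0.6
fa,16:1n-9,0.1,0.0,0.6,0.2,0.1,0.0,1.8,0.1
fa,16:1n-5,0.3,0.0,2.5,0.0,0.1,0.0,1.0,0.2
fa,17:0,trace,,0.2,0.0,trace,,0.7,0.1
fa,18:0,0.2,0.0,1.9,0.2,0.3,0.2,5.7,0.8
fa,18:1n-9,0.2,0.0,2.2,0.2,0.2,0.1,4.4,0.5
fa,18:1n-7,0.1,0.0,0.8,0.0,0.1,0.1,2.4,0.5
fa,18:2n-6,1.1,0.0,10.0,0.1,0.4,0.1,8.1,1.1
fa,18:3n-3,5.8,0.5,54.9,1.9,1.8,0.6,33.5,1.3
fa,20:0,0.1,0.0,1.1,0.2,0.1,0.0,1.7,0.3
fa,22:0,0.2,0.0,1.8,0.4,0.1,0.0,1.9,0.3
class,SFA,3.1,0.1,29.1,2.2,2.6,1.1,48.7,1.3
class,UFA,7.5,0.7,70.9,2.2,2.7,1.0,51.3,1.3
total,Total FA,10.6,0.6,,,5.3,2.1,,
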
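name,delta_d,delta_p,delta_h,synonyms,source
water,15.5,16.0,42.3,,hansen-handbook
methanol,15.1,12.3,22.3,MeOH,hansen-handbook
ethanol,15.8,8.8,19.4,EtOH,hansen-handbook
1-propanol,16.0,6.8,17.4,n-propanol;propan-1-ol,hansen-handbook
1-butanol,16.0,5.7,15.8,n-butanol;butan-1-ol,hansen-handbook
1-octanol,17.0,3.3,11.9,n-octanol;octan-1-ol,hansen-handbook
acetone,15.5,10.4,7.0,propanone,hansen-handbook
methyl ethyl ketone,16.0,9.0,5.1,MEK;2-butanone;butanone,hansen-handbook
methyl isobutyl ketone,15.3,6.1,4.1,MiBK;MIBK;4-methyl-2-pentanone,hansen-handbook
acetonitrile,15.3,18.0,6.1,ACN;MeCN,hansen-handbook
ethyl acetate,15.8,5.3,7.2,EtOAc;ETAC,hansen-handbook
n-propyl acetate,15.3,4.3,7.6,propyl acetate;nPAc,hansen-handbook
isopropyl acetate,14.9,4.5,8.2,IPAc;iPAc,hansen-handbook
n-butyl acetate,15.8,3.7,6.3,butyl acetate;nBuAc,hansen-handbook
ethyl lactate,16.0,7.6,12.5,,hansen-handbook
n-hexane,14.9,0.0,0.0,hexane,hansen-handbook
n-decane,15.7,0.0,0.0,decane,hansen-handbook
cyclohexane,16.8,0.0,0.2,,hansen-handbook
cyclooctane,17.3,0.0,0.0,,hansen-handbook
diisopropyl ether,13.7,3.9,2.3,DIPE;isopropyl ether,hansen-handbook
p-xylene,17.8,1.0,3.1,para-xylene,hansen-handbook
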
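region_code,name,lon,lat
BJ,北京,116.41,40.19
TJ,天津,117.33,39.29
HE,河北,115.66,38.90
SX,山西,112.41,37.72
NM,内蒙古,113.94,44.09
LN,辽宁,122.60,41.30
JL,吉林,126.19,43.67
HL,黑龙江,128.05,47.86
SH,上海,121.45,31.21
JS,江苏,119.45,32.98
ZJ,浙江,120.10,29.18
AH,安徽,117.22,31.82
FJ,福建,117.98,26.07
JX,江西,115.72,27.62
SD,山东,118.19,36.34
HA,河南,113.62,33.88
HB,湖北,112.27,31.16
HN,湖南,111.71,27.61
GD,广东,113.43,23.34
GX,广西,108.79,23.83
HI,海南,109.75,19.19
CQ,重庆,107.87,30.06
SC,四川,102.69,30.65
GZ,贵州,106.88,26.82
YN,云南,101.49,25.04
XZ,西藏,88.39,31.56
SN,陕西,108.89,35.19
GS,甘肃,100.94,37.78
QH,青海,96.04,35.72
NX,宁夏,106.17,37.27
XJ,新疆,85.25,41.11
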
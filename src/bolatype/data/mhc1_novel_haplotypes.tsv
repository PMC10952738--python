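haplotype	allele1	allele2	allele3	allele4	obs	pct
HP1.100.2	4*063:01	2*032:AAN	3*078:01/3*078:02		7	0.43
HP1.101.2	2*089:AB	4*094:01	3*004:04/3*083:01		3	0.19
HP1.102.2	2*075:01	3*004:04/3*083:01	4*095:01		5	0.31
HP1.111.1	1*028:AC	2*054:AA:01			11	0.68
HP1.112.1	3*068:01	2*032:02			4	0.25
HP1.113.1	1*042:AA	MHCI*cm22:01			17	1.05
HP1.115.1	3*038:AB	3*004:04/3*083:01	6*090:AC		5	0.31
HP1.116.1	MHCI*zm1:01	MHCI*cm41:05	3*004:02:AC		28	1.73
HP1.116.2	MHCI*zm1:02	MHCI*cm41:05	3*004:02:AC		3	0.19
HP1.117.1	4*063:01	2*057:AB	3*078:01/3*078:02		7	0.43
HP1.118.1	2*069:AA	1*067:AA			77	4.75
HP1.119.1	2*022:AA	MHCI*cm24:01			3	0.19
HP1.12.5	3*073:AE	3*004:AB	MHCI*cm1:02	6*090:01	94	5.8
HP1.12.7	3*073:AD	3*004:AB:01	6*090:01		11	0.68
HP1.120.1	MHCI*cm4:01	2*016:01:AA	3*087:01:AA		2	0.12
HP1.122.1	MHCI*zm22:01	MHCI*zm18:01	6*040:01	MHCI*zm16:01	5	0.31
HP1.123.1	3*050:AC	3*004:04/3*083:01	2*025:01	6*040:01	17	1.05
HP1.124.1	3*050:AF	3*037:01			2	0.12
HP1.125.1	2*030:01:AA	MHCI*zm19:01	MHCI*cm1:01		19	1.17
HP1.126.1	MHCI*zm23:01	2*048:01	3*078:01/3*078:02		5	0.31
HP1.127.1	MHCI*zm21:01	MHCI*cm13:01			2	0.12
HP1.128.1	MHCI*zm21:01	2*048:01			10	0.62
HP1.129.1	2*047:AB	1*097:01:AA			8	0.49
HP1.130.1	2*070:01	5*072:01			8	0.49
HP1.131.1	2*071:AA	MHCI*br28:01	6*090:AA		21	1.3
HP1.132.1	BoLA-3*011:01	BoLA-2*048:01	BoLA-3*078:01/BoLA-3*078:02		2	0.12
HP1.133.1	MHCI*cm4:08	2*048:01	3*004:02/3*053:01/3*081:01		6	0.37
HP1.134.1	MHCI*br32:01	MHCI*zm7:01			11	0.68
HP1.135.1	5*072:01	6*090:AB			16	0.99
HP1.136.1	MHCI*br30:01	4*094:01:AA	3*098:01N		62	3.82
HP1.137.1	MHCI*br7:01	MHCI*zm8:01	2*006:01/2*006:02/2*006:03	3*078:01/3*078:02	4	0.25
HP1.138.1	MHCI*cm9:02	4*094:AB	3*004:04/3*083:01	MHCI*cm1:03	2	0.12
HP1.139.1	MHCI*cm38:01	2*047:01	3*078:01/3*078:02		4	0.25
HP1.14.2	MHCI*cm10:01	3*004:02/3*053:01/3*081:01	MHCI*cm13:01		13	0.8
HP1.140.1	3*050:AE	2*047:01	3*004:04/3*083:01		26	1.6
HP1.142.1	MHCI*zm3:01	3*017:AD	2*055:01	3*033:01N	4	0.25
HP1.149.1	1*009:AD	6*090:01			14	0.86
HP1.156.2	3*050:AE	3*004:04/3*083:01			3	0.19
HP1.20.4	MHCI*cm8:04	MHCI*cm40:02			28	1.73
HP1.21.2	MHCI*cm9:03	3*017:AB	3*004:02:AB	6*092:AA	16	0.99
HP1.46.4	MHCI*cm4:08	2*008:AA	3*004:02/3*053:01/3*081:01	6*091:01	7	0.43
HP1.46.5	MHCI*cm4:08	2*008:AA	3*004:04/3*083:01	6*091:01	4	0.25
HP1.5.5	1*029:AC:01	2*030:01:AA	MHCI*cm1:01		7	0.43
HP1.5.6	1*029:AE	2*030:01:AA	MHCI*cm1:01		4	0.25
HP1.51.2	2*022:AE	1*074:01			13	0.8
HP1.52.3	MHCI*gb20:01	3*004:02/3*053:01/3*081:01	2*016:02/2*016:03	6*091:01	7	0.43
HP1.69.2	3*080:AA	2*057:01	3*033:01N	6*090:01	6	0.37
HP1.79.2	MHCI*br7:01	MHCI*br15:02			25	1.54
HP1.95.2	MHCI*br1:02	3*004:03			15	0.93
HP1.95.3	MHCI*br1:03	3*004:03			18	1.11
HP1.96.2	MHCI*br9:02	2*060:01	6*093:01		8	0.49
HP1.A13.3	1*031:02	2*032:ACN			2	0.12
HP1.A15.3	1*009:AC	4*024:01:01:01/4*024:01:01:02	2*025:01		2	0.12
HP1.A15v.3	1*009:AA	4*024:01:01:01/4*024:01:01:02	6*040:01	2*025:AA	2	0.12
HP1.A20v.2	3*027:02	2*026:04			5	0.31
HP1.H2.2	5*039:AA				2	0.12
unHP1.10.2	3*038:01:AA	2*096:01:AB	3*004:02/3*053:01/3*081:01		1	0.06
unHP1.102.3	2*075:01	3*004:04/3*083:01	4*095:AB		1	0.06
unHP1.110.1	MHCI*zm5:01	2*008:02/2*008:03	2*006:01/2*006:02/2*006:03		1	0.06
unHP1.114.1	MHCI*zm9:01	2*008:AC			1	0.06
unHP1.115.2	3*038:AD	3*004:04/3*083:01	6*090:01		1	0.06
unHP1.121.1	MHCI*zm29:01	MHCI*zm28:01			1	0.06
unHP1.129.2	2*047:AB	1*097:01			1	0.06
unHP1.141.1	MHCI*br29:01	2*032:AAN	2*008:AB		1	0.06
unHP1.143.1	3*050:AE	3*004:04/3*083:01	MHCI*cm9:03		1	0.06
unHP1.144.1	MHCI*zm2:01	2*048:01	3*078:01/3*078:02		1	0.06
unHP1.145.1	2*079:01	6*091:01	MHCI*gb5:01		1	0.06
unHP1.146.1	1*021:01	2*054:AA:01			1	0.06
unHP1.147.1	2*005:01	3*052:01	3*004:04/3*083:01		1	0.06
unHP1.148.1	MHCI*zm11:01	4*077:01	3*033:ABN		1	0.06
unHP1.44.3	MHCI*ke1:03	3*004:AD	6*090:01		1	0.06
unHP1.55.1	MHCI*cm10:01	3*004:AA:01	MHCI*ke5:01		1	0.06
unHP1.61.2	3*066:AB	3*004:03			1	0.06
unHP1.66.2	2*005:AA	3*087:01:AA	MHCI*ke8:04		1	0.06
unHP1.79.3	MHCI*br7:02	MHCI*br15:01			1	0.06
unHP1.A13.4	1*031:AA	2*032:01N			1	0.06
unHP1.A15v.4	1*009:AA	4*024:01:01:01/4*024:01:01:02	2*025:01	6*040:AE	1	0.06
unHP1.A19.2	6*014:01	2*016:01			1	0.06
unHP1.A19v.2	6*014:02:AA	2*016:01	MHCI*cm36:01		1	0.06
unHP1.A20.2	3*027:AA	2*026:04			1	0.06
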
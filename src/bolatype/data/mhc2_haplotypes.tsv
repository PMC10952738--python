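haplotype	prev	drb3	dqa1	dqb1	dqa2	dqb2	hf_n	zm_n	dqa1_presumed
DR10.1|DQ10.2|DQ6.1	DH03A	010:01	010:04	010:02:01	021:02	009:01	100	0
DR1.1|DQ1.1	DH24A	001:01	001:01	001:01			95	3	1
DR11.1|DQ10.1|DQ5.1	DH22H	011:01	010:03	010:02:01	034:01	014:02	94	0
DR15.1|DQ10.1|DQ4.1	DH16A	015:01	010:03	010:02:01	022:09	013:01	85	34
DR14.1|DQ14.1	DH27A	014:01:01	014:01:01	014:01			53	59	1
DR12.1|DQ12.1|DQ17.1	DH08A	012:01	012:05	010:05	022:08	012:01	39	16
DR27.3|DQ1.2|DQ11.1		027:03	?	001:05	028:02	020:02	36	0
DR18.1|DQ13.1|DQ15.1	DH18A	018:01	025:01:02	006:01	022:08	017:02	29	0
DR9.2|DQ3.1	0902B	009:02/049:01	002:07	018:03			27	17
DR7.1|DQ1.2|DQ11.1		007:01	?	001:05	028:02	020:02	25	21
DR16.1|DQ12.3|DQ4.1	1601C	016:01	012:06	010:01	022:09	013:01	22	1
DR6.1|DQ13.1|DQ16.1	0601A	006:01	025:01:02	006:01	024:AA	003:02	17	1
DR2.1|DQ2.1	DH07A	002:01	002:03	002:01			11	24
DR5.1|DQ13.1|DQ4.1	DH01A	005:01	025:01:02	006:01	022:09	013:01	5	0
DR5.1|DQ13.1|DQ9.1		005:01	025:01:02	006:01	022:08	005:01	3	0
DR11.1|DQ10.2|DQ7.1	DH22E	011:01	010:04	010:02:01	021:02	029:02	3	0
DR11.1|DQ12.3|DQ4.1		011:01	012:06	010:01	022:09	013:01	3	0
DR20.1|DQ25.1		020:01:01	?	025:01			2	33
DR27.3|DQ12.2|DQ9.1	2703E	027:03	012:05:AA	010:01	022:08	005:01	2	0
unDR18.1|DQ53.1|DQ52.1		018:01	?	018:03	023:01	gb1:01	1	0
DR30.1|DQ18.1		030:01	002:02	004:02			0	76
DR18.1|DQ37.1|DQ52.1		018:01	023:01	003:02	?	gb1:01	0	70
DR28.1|DQ39.1|DQ15.1		028:01/028:04	026:03	006:01	022:08	017:02	0	67
DR24.1|DQ25.2		024:01/024:07	?	025:02			0	50
DR13.AA|DQ38.1|DQ49.1		013:AA	026:02	030:01	029:01	016:02	0	47
DR21.1|DQ24.1		021:01	003:01	015:01			0	43
DR3.2|DQ19.2		003:02:01	002:07	003:02			0	42
DR16.1|DQ33.1|DQ46.1		016:01	012:05:AA	041:01	022:08	009:01	0	41
DR11.3|DQ21.1	1103A	011:03	002:03	036:02			0	38
DR22.1|DQ41.3		022:01	027:04	zm1:01			0	38
DR19.1|DQ12.3|DQ47.1		019:01	012:06	010:01	022:08	031:AA	0	31
DR21.1|DQ27.3		021:01	003:01	018:06:AA			0	29
DR22.1|DQ40.4|DQ9.2		022:01	027:01:AA	007:01	022:08	005:02	0	25
DR44.1|DQ44.1		044:01	?	027:01			0	25
DR28.1|DQ13.1|DQ15.1		028:01/028:04	025:01:02	006:01	022:08	017:02	0	22
DR10.2|DQ26.1		010:02	?	026:01			0	20
DR33.1|DQ30.2		033:01	001:AA	004:02			0	19
DR26.1|DQ10.4|DQ46.1		026:01	010:04	010:09	022:08	009:01	0	18
DR25.1|DQ36.1|DQ11.2		025:01:01	013:01	032:01	028:02:AA	020:01	0	18
DR25.1|DQ26.1		025:01:01	?	026:01			0	17
DR13.AA|DQ40.1		013:AA	027:01:01	007:AA			0	15
DR27.4|DQ29.1|DQ11.3		027:04	004:01	018:09	028:AB	020:AC	0	15
DR28.2|DQ34.1		028:02	013:01	018:02			0	15
DR3.2|DQ25.1		003:02:01	?	025:01			0	11
DR12.1|DQ12.1|DQ46.1		012:01	012:05	010:05	022:08	009:01	0	10
DR16.1|DQ10.2|DQ45.1		016:01	010:04	010:02:01	021:02	017:02	0	10
DR29.2|DQ42.1		029:02	030:01	zm1:03			0	10
DR20.3|DQ25.1		020:03	?	025:01			0	9
DR16.1|DQ53.1|DQ46.1		016:01	?	041:01	022:08	009:01	0	9
DR31.1|DQ32.1		031:01	008:03	024:01			0	9
DR23.1|DQ29.1|DQ11.3		023:01	004:01	018:09	028:AB	020:AC	0	8
DR13.2|DQ41.1	1302A	013:02	027:01:01	zm1:01			0	8
DR31.1|DQ38.1|DQ4.1		031:01	026:02	030:01	022:09	013:01	0	8
DR42.1|DQ27.2		042:01	003:01	018:05			0	8
DR20.5|DQ25.1		020:05	?	025:01			0	7
DR48.2|DQ25.1		048:02	?	025:01			0	7
DR10.2|DQ29.1|DQ11.3		010:02	004:01	018:09	028:AB	020:AC	0	7
DR32.2|DQ40.2		032:02	027:01:01	007:AB			0	7
DR10.1|DQ12.3|DQ4.1		010:01	012:06	010:01	022:09	013:01	0	7
DR39.1|DQ8.2		039:01	008:03	008:02			0	7
DR20.1.AA|DQ25.1		020:01:AA	?	025:01			0	6
DR13.AA|DQ40.3		013:AA	027:01:01	007:AC			0	6
DR11.3|DQ19.1		011:03	002:03	003:02			0	6
DR27.5|DQ35.1		027:05	013:01	019:01			0	6
DR16.2|DQ1.1		016:02	?	001:01			0	6
DR3.2|DQ3.1		003:02:01	002:07	018:03			0	5
DR3.1|DQ19.2		003:01	002:07	003:02			0	5
DR36.1|DQ34.1		036:01	013:01	018:02			0	5
DR5.1|DQ13.1|DQ15.1		005:01	025:01:02	006:01	022:08	017:02	0	4
DR4.1|DQ36.1|DQ11.2		004:01	013:01	032:01	028:02:AA	020:01	0	4
DR14.1|DQ12.3|DQ4.1		014:01:01	012:06	010:01	022:09	013:01	0	4
DR26.1|DQ33.2|DQ46.1		026:01	012:AA	041:01	022:08	009:01	0	4
DR36.1|DQ12.5|DQ4.2		036:01	012:05:AA	010:02:01	022:09	013:02	0	4
DR4.1|DQ18.2		004:01	002:AA	004:01			0	4
DR5.2|DQ41.2		005:02	027:03	zm1:03			0	4
DR10.2|DQ26.1|DQ11.2		010:02	?	026:01	028:02:AA	020:01	0	4
DR16.1|DQ10.2|DQ9.1		016:01	010:04	010:02:01	022:08	005:01	0	4
DR4.2|DQ18.3|DQ51.1		004:02	002:AA	004:02	zm1:01	020:AB	0	4
DR41.1|DQ13.1|DQ16.1		041:01	025:01:02	006:01	024:AA	003:02	0	3
DR19.1|DQ36.1|DQ11.2		019:01	013:01	032:01	028:02:AA	020:01	0	3
DR30.1|DQ43.1		030:01	?	004:02			0	3
DR5.2|DQ38.1|DQ48.1		005:02	026:02	030:01	029:01	014:02	0	3
DR9.1|DQ33.2|DQ46.1		009:01	012:AA	041:01	022:08	009:01	0	3
DR9.2|DQ28.1		009:02/049:01	003:01	033:02			0	3
DR7.1|DQ1.2|DQ51.1		007:01	?	001:05	zm1:01	020:AB	0	3
DR8.1|DQ8.1|DQ11.2		008:01	008:01	008:01	028:02:AA	020:01	0	3
DR15.1|DQ10.3|DQ4.1		015:01	010:03	010:01	022:09	013:01	0	3
DR20.AB|DQ31.1		020:AB	008:01	022:01			0	3
DR27.3|DQ1.1		027:03	?	001:01			0	3
DR10.1|DQ27.3		010:01	003:01	018:06:AA			0	2
DR16.1|DQ12.3|DQ47.1		016:01	012:06	010:01	022:08	031:AA	0	2
DR16.1|DQ12.2|DQ9.1		016:01	012:05:AA	010:01	022:08	005:01	0	2
DR48.2|DQ8.1|DQ11.2		048:02	008:01	008:01	028:02:AA	020:01	0	2
DR23.1|DQ30.1		023:01	001:02	004:02			0	2
DR15.1|DQ10.1|DQ50.1		015:01	010:03	010:02:01	034:01	029:03	0	2
DR35.1|DQ23.1		035:01	002:08	022:01			0	2
unDR21.1|DQ25.1		021:01	?	025:01			0	1
unDR24.1|DQ3.1		024:01/024:07	002:07	018:03			0	1
unDR17.3|DQ20.1		017:03	002:03	023:01			0	1
unDR7.1|DQ12.3|DQ47.1		007:01	012:06	010:01	022:08	031:AA	0	1
unDR15.1|DQ26.1		015:01	?	026:01			0	1
unDR22.1|DQ40.5		022:01	027:04	007:AC			0	1
unDR27.3|DQ35.1		027:03	013:01	019:01			0	1
unDR16.1|DQ10.2|DQ17.1		016:01	010:04	010:02:01	022:08	012:01	0	1
unDR22.1|DQ8.1|DQ11.2		022:01	008:01	008:01	028:02:AA	020:01	0	1
unDR10.1|DQ12.2|DQ45.1		010:01	012:05:AA	010:01	021:02	017:02	0	1
unDR19.1|DQ12.3|DQ46.1		019:01	012:06	010:01	022:08	009:01	0	1
unDR27.7|DQ27.1		027:07	003:01	018:03			0	1
unDR39.1|DQ1.1		039:01	?	001:01			0	1
unDR7.1|DQ14.1		007:01	?	014:01			0	1
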
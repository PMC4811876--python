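locus_id	short_name	strand	position
Vitvi12g00665	PAT1	-	8738265-8739902
Vitvi19g00619	PAT2	-	7772106-7773743
Vitvi10g00271	PAT3	-	2802206-2803843
Vitvi19g00392	PAT4	-	5276148-5277899
Vitvi16g01086	PAT6	+	19383904-19385748
Vitvi04g01696	PAT7	-	23747087-23748793
Vitvi18g01210	PAT8	+	13411198-13412895
Vitvi07g01612	SHR5	+	21912240-21913607
Vitvi12g00571	SHR4	+	7509331-7510668
Vitvi09g01487	SHR3	-	910682-912319
Vitvi05g01554	SHR2	+	23894334-23895644
Vitvi07g02073	SHR1	-	21633666-21635150
Vitvi06g00491	LISCL1	+	5938487-5940601
Vitvi06g00490	LISCL4	+	5930838-5932814
Vitvi06g00492	LISCL2	+	5942791-5944119
Vitvi06g01569	LISCL12	+	5918887-5921169
Vitvi06g00489	LISCL3	+	5925910-5928204
Vitvi08g01214	LISCL5	+	14792851-14795082
Vitvi13g00312	LISCL6	+	3256665-3258887
Vitvi13g00314	LISCL8	+	3283478-3285724
Vitvi13g00311	LISCL9	+	3251727-3254009
Vitvi13g01865	LISCL10	+	3279518-3281677
Vitvi13g01864	LISCL11	+	3274050-3274663, 3274680-3276222
Vitvi13g00313	LISCL7	+	3270544-3270684, 3270692-3271508, 3271694-3271929, 3271938-3272162
Vitvi01g00446	RGA5	-	4895406-4897178
Vitvi14g00841	RGA4	+	14807005-14808846
Vitvi11g00409	RGA3	-	3959545-3961143
Vitvi01g01509	GRASV1b	+	20426662-20428254
Vitvi17g01040	GRASV1d	-	12688373-12689932
Vitvi19g01706	GRASV1a	+	23595896-23597488
Vitvi14g01510	GRASV1c	-	25316395-25317516, 25317604-25318488
Vitvi07g00627	SCR3	+	6996793-6998256
Vitvi03g01226	SCR2	+	19152243-19153571
Vitvi08g00007	SCR1	-	115793-116261, 116647-117596
Vitvi06g01133	SCL3a	+	15915179-15916597
Vitvi02g00974	SCL3b	+	13518884-13519177
Vitvi13g01556	SCL3c	-	24957576-24959012
Vitvi14g01348	SCL3d	+	23412635-23413888
Vitvi18g01322	GRAS8b	+	14926630-14927997
Vitvi02g00370	GRAS8a	+	3323726-3325756
Vitvi04g01281	LAS2	+	18563606-18565456
Vitvi19g00932	LAS1	+	10747971-10749212
Vitvi07g00418	GRASV2a	-	4408615-4410429
Vitvi05g00110	GRASV2b	-	1038770-1039128, 1039236-1039324, 1039452-1040602
Vitvi08g00751	GRASV3a	-	9219561-9220028, 9220132-9221151
Vitvi08g00746	GRASV3b	-	9152326-9153933
Vitvi08g01969	GRASV3c	+	9227520-9229388
Vitvi04g01622	SCL26a	+	22393173-22394627
Vitvi18g00300	SCL26b	-	3254592-3256064
Vitvi04g01247	HAM3	-	18244582-18246198
Vitvi02g00536	HAM1	+	5144861-5147299
Vitvi15g00680	HAM2	-	14397074-14399326
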
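gene	direction	location	size	intergenic
cox1	F	1–1560	1560	−25
trnL2	F	1536–1604	69	5
cox2	F	1610–2317	708	−20
trnK	F	2298–2366	69	0
trnD	F	2367–2434	68	0
atp8	F	2435–2593	159	−7
atp6	F	2587–3261	675	−1
cox3	F	3261–4052	792	−1
trnG	F	4052–4116	65	0
nad3	F	4117–4467	351	2
trnA	F	4470–4536	67	10
trnR	F	4547–4612	66	2
trnN	F	4615–4681	67	0
trnS1	F	4682–4748	67	1
trnE	F	4750–4815	66	4
trnH	R	4820–4884	65	0
trnF	R	4885–4950	66	1
nad5	R	4952–6682	1731	41
nad4	R	6742–8073	1350	−7
nad4L	R	8067–8369	303	8
trnT	F	8378–8443	66	0
trnP	R	8444–8509	66	2
nad6	F	8512–9015	504	−1
cob	F	9015–10,149	1135	0
trnS2	F	10,150–10,217	68	15
nad1	R	10,233–11,171	939	34
trnL1	R	11,206–11,271	66	0
rrnL	R	11,272–12,612	1341	0
trnV	R	12,613–12,685	73	0
rrnS	R	12,686–13,515	830	0
CR	—	13,516–14,193	678	0
trnQ	R	14,194–14,263	70	23
trnI	F	14,287–14,354	68	8
trnM	F	14,363–14,431	69	0
nad2	F	14,432–15,439	1008	2
trnW	F	15,442–15,511	70	−3
trnC	R	15,509–15,573	65	0
trnY	R	15,574–15,641	68	–
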
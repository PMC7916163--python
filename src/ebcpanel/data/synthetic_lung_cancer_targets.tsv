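mirna	gene	evidence	lung_cancer_associated
miR-5001-5p	BCL2L1	high_confidence_predicted	true
miR-5001-5p	BCL2	experimentally_observed	true
miR-5001-5p	CDKN2B	experimentally_observed	true
miR-5001-5p	IKBKG	high_confidence_predicted	true
miR-5001-5p	EGFR	high_confidence_predicted	true
miR-5001-5p	TP53	experimentally_observed	true
miR-5001-5p	PTEN	experimentally_observed	true
miR-5001-5p	KRAS	experimentally_observed	true
miR-5001-5p	AKT1	low_confidence_predicted	true
miR-5001-5p	STAT3	high_confidence_predicted	true
miR-5001-5p	CYCS	high_confidence_predicted	true
miR-5001-5p	CDKN2A	experimentally_observed	true
miR-6780a-5p	AKT1	high_confidence_predicted	false
miR-6780a-5p	CYCS	low_confidence_predicted	true
miR-6780a-5p	RASD1	high_confidence_predicted	true
miR-6780a-5p	PTEN	experimentally_observed	true
miR-6780a-5p	CDKN2A	high_confidence_predicted	false
miR-6780a-5p	CDK6	high_confidence_predicted	true
miR-6780a-5p	TP53	high_confidence_predicted	true
miR-6780a-5p	BCL2	experimentally_observed	true
miR-6780a-5p	NFKB1	experimentally_observed	false
miR-6780a-5p	TGFA	high_confidence_predicted	true
miR-6780a-5p	IKBKG	high_confidence_predicted	true
miR-6780a-5p	KRAS	high_confidence_predicted	true
miR-6780a-5p	BCL2L1	high_confidence_predicted	true
miR-6780a-5p	STK4	high_confidence_predicted	true
miR-6794-5p	PTEN	low_confidence_predicted	true
miR-6794-5p	EGFR	experimentally_observed	true
miR-6794-5p	STAT3	experimentally_observed	true
miR-6794-5p	RB1	low_confidence_predicted	true
miR-6794-5p	CYCS	high_confidence_predicted	true
miR-6794-5p	NFKB1	high_confidence_predicted	true
miR-6794-5p	IKBKG	high_confidence_predicted	true
miR-6794-5p	KRAS	high_confidence_predicted	true
miR-6794-5p	TRAF1	low_confidence_predicted	false
miR-6794-5p	AKT1	experimentally_observed	true
miR-6794-5p	CDKN2B	low_confidence_predicted	true
miR-5006-5p	CDK6	low_confidence_predicted	true
miR-5006-5p	TP53	high_confidence_predicted	true
miR-5006-5p	PTEN	experimentally_observed	true
miR-5006-5p	STAT3	experimentally_observed	false
miR-5006-5p	TGFA	experimentally_observed	true
miR-5006-5p	NFKB1	experimentally_observed	true
miR-5006-5p	STK4	low_confidence_predicted	false
miR-5006-5p	CDKN2A	high_confidence_predicted	true
miR-5006-5p	IKBKG	high_confidence_predicted	true
miR-5006-5p	BCL2L1	experimentally_observed	true
miR-5006-5p	EGFR	high_confidence_predicted	true
miR-5006-5p	CYCS	experimentally_observed	true
miR-5006-5p	MYC	low_confidence_predicted	true
miR-5006-5p	AKT1	low_confidence_predicted	true
miR-1908-5p	MYC	experimentally_observed	true
miR-1908-5p	BCL2	experimentally_observed	true
miR-1908-5p	CDKN2A	experimentally_observed	false
miR-1908-5p	CDK6	experimentally_observed	true
miR-1908-5p	BCL2L1	high_confidence_predicted	true
miR-1908-5p	EGFR	high_confidence_predicted	true
miR-1908-5p	PTEN	high_confidence_predicted	true
miR-1908-5p	TGFA	experimentally_observed	true
miR-1908-5p	TP53	high_confidence_predicted	true
miR-1908-5p	AKT1	high_confidence_predicted	true
miR-1908-5p	IKBKG	high_confidence_predicted	true
miR-1908-5p	RB1	high_confidence_predicted	true
miR-1233-5p	BCL2	experimentally_observed	true
miR-1233-5p	TP53	high_confidence_predicted	true
miR-1233-5p	STAT3	low_confidence_predicted	true
miR-1233-5p	MYC	low_confidence_predicted	true
miR-1233-5p	TGFA	high_confidence_predicted	true
miR-1233-5p	BCL2L1	high_confidence_predicted	true
miR-1233-5p	RASD1	experimentally_observed	true
miR-1233-5p	PTEN	high_confidence_predicted	true
miR-1233-5p	CDKN2B	high_confidence_predicted	true
miR-1233-5p	EGFR	experimentally_observed	true
miR-1233-5p	STK4	experimentally_observed	true
miR-6803-5p	BCL2L1	high_confidence_predicted	true
miR-6803-5p	TGFA	high_confidence_predicted	true
miR-6803-5p	TP53	experimentally_observed	false
miR-6803-5p	CDK6	low_confidence_predicted	true
miR-6803-5p	AKT1	experimentally_observed	true
miR-6803-5p	STK4	low_confidence_predicted	true
miR-6803-5p	RASD1	high_confidence_predicted	true
miR-6803-5p	BCL2	high_confidence_predicted	true
miR-6803-5p	CDKN2A	experimentally_observed	true
miR-6803-5p	CYCS	experimentally_observed	true
miR-6803-5p	RB1	high_confidence_predicted	false
miR-6803-5p	IKBKG	high_confidence_predicted	true
miR-6865-5p	MYC	experimentally_observed	true
miR-6865-5p	AKT1	high_confidence_predicted	true
miR-6865-5p	PTEN	high_confidence_predicted	true
miR-6865-5p	STK4	low_confidence_predicted	true
miR-6865-5p	CYCS	low_confidence_predicted	true
miR-6865-5p	IKBKG	low_confidence_predicted	true
miR-6865-5p	TGFA	high_confidence_predicted	true
miR-6865-5p	CDKN2B	experimentally_observed	true
miR-6865-5p	CDK6	high_confidence_predicted	true
miR-6865-5p	NFKB1	experimentally_observed	true
miR-6865-5p	TP53	experimentally_observed	true
miR-6777-5p	CDKN2A	high_confidence_predicted	true
miR-6777-5p	TRAF1	high_confidence_predicted	true
miR-6777-5p	RASD1	high_confidence_predicted	false
miR-6777-5p	PTEN	experimentally_observed	true
miR-6777-5p	TP53	experimentally_observed	false
miR-6777-5p	EGFR	low_confidence_predicted	true
miR-6777-5p	NFKB1	experimentally_observed	true
miR-6777-5p	RB1	experimentally_observed	true
miR-6777-5p	CYCS	experimentally_observed	true
miR-6777-5p	BCL2L1	high_confidence_predicted	true
miR-6777-5p	STK4	experimentally_observed	true
miR-6777-5p	IKBKG	experimentally_observed	true
miR-6777-5p	MYC	experimentally_observed	true
miR-6777-5p	CDK6	experimentally_observed	true
miR-4507	CDK6	high_confidence_predicted	true
miR-4507	TRAF1	low_confidence_predicted	true
miR-4507	CDKN2A	low_confidence_predicted	true
miR-4507	CDKN2B	high_confidence_predicted	true
miR-4507	IKBKG	high_confidence_predicted	true
miR-451a	TGFA	high_confidence_predicted	false
miR-451a	TRAF1	low_confidence_predicted	true
miR-451a	KRAS	high_confidence_predicted	true
miR-8075	RB1	experimentally_observed	true
miR-8075	TP53	high_confidence_predicted	true
miR-4529-3p	STK4	experimentally_observed	true
miR-4529-3p	KRAS	experimentally_observed	true
miR-4529-3p	EGFR	experimentally_observed	true
miR-4529-3p	PTEN	low_confidence_predicted	true
miR-4529-3p	TRAF1	high_confidence_predicted	true
miR-7704	EGFR	low_confidence_predicted	true
miR-7704	CDKN2B	experimentally_observed	true
miR-7704	STK4	low_confidence_predicted	true
miR-602	KRAS	experimentally_observed	true
miR-602	STK4	experimentally_observed	false
miR-602	CYCS	experimentally_observed	true
miR-602	RB1	high_confidence_predicted	true
miR-551b-5p	TGFA	low_confidence_predicted	false
miR-551b-5p	BCL2L1	experimentally_observed	true
miR-551b-5p	NFKB1	low_confidence_predicted	true
miR-1272	CDKN2B	low_confidence_predicted	true
miR-1272	IKBKG	high_confidence_predicted	true
miR-548x-3p	RB1	experimentally_observed	true
miR-548x-3p	STAT3	low_confidence_predicted	true
miR-548x-3p	EGFR	low_confidence_predicted	true
miR-548x-3p	NFKB1	experimentally_observed	true
miR-548x-3p	STK4	high_confidence_predicted	true
miR-548x-3p	CDKN2A	high_confidence_predicted	true
miR-877-5p	BCL2	high_confidence_predicted	true
miR-877-5p	EGFR	experimentally_observed	true
miR-877-5p	AKT1	low_confidence_predicted	true
miR-877-5p	CDK6	low_confidence_predicted	true
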
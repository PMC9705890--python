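product_id	product_type	label_claim	detected_subspecies
A1	Probiotic product (powder, Korea)	L. delbrueckii subsp. bulgaricus	bulgaricus
A2	Probiotic product (powder, Korea)	L. delbrueckii subsp. bulgaricus	bulgaricus
A3	Probiotic product (capsules, Canada)	L. delbrueckii subsp. bulgaricus	bulgaricus
A4	Probiotic product (capsules, Canada)	L. delbrueckii subsp. bulgaricus	bulgaricus
A5	Probiotic product (powder, Korea)	L. delbrueckii subsp. bulgaricus	bulgaricus
A6	Probiotic product (capsules, Korea)	L. bulgaricus	bulgaricus
A7	Probiotic product (capsules, USA)	L. bulgaricus	bulgaricus
A8	Probiotic product (capsules, USA)	L. bulgaricus	bulgaricus
A9	Probiotic product (powder, Korea)	L. bulgaricus	bulgaricus
A10	Probiotic product (powder, Korea)	L. bulgaricus	bulgaricus
A11	Probiotic product (capsules, Canada)	L. bulgaricus	bulgaricus
A12	Probiotic product (powder, Korea)	L. bulgaricus	bulgaricus
A13	Probiotic product (capsules, Canada)	L. bulgaricus	bulgaricus
A14	Probiotic product (powder, Korea)	L. bulgaricus	bulgaricus
A15	Probiotic product (powder, Korea)	L. bulgaricus	bulgaricus
B1	Dairy product (yogurt, Korea)	L. bulgaricus	bulgaricus
B2	Dairy product (yogurt, Korea)	L. bulgaricus	bulgaricus
B3	Dairy product (yogurt, Korea)	L. bulgaricus	bulgaricus
B4	Dairy product (yogurt, Korea)	L. bulgaricus	bulgaricus
B5	Dairy product (yogurt, Korea)	L. bulgaricus	bulgaricus
B6	Dairy product (yogurt, Korea)	L. bulgaricus	bulgaricus
B7	Dairy product (yogurt, Korea)	Lactic acid bacteria	bulgaricus
B8	Dairy product (yogurt, Korea)	Lactic acid bacteria	bulgaricus
B9	Dairy product (yogurt, Korea)	Lactic acid bacteria	bulgaricus
B10	Dairy product (yogurt, Korea)	Lactic acid bacteria	bulgaricus
B11	Dairy product (yogurt, Korea)	Lactic acid bacteria	bulgaricus
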
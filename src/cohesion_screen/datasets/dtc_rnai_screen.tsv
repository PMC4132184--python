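# DTC-migration RNAi screen: gonad-arm outcomes per treatment (percent of arms, n arms scored).
# Treatments with NA in the n column arrested as early-stage larvae and could not be scored.
treatment	normal	extra_turn	wandering	overshoot	other	n
control	99%	0%	1%	0%	0%	102
W03H9.4	25%	13%	11%	46%	4%	114
C07A9.2	48%	3%	9%	34%	5%	96
EEED8.5	25%	7%	11%	54%	3%	100
F49D11.1	50%	4%	7%	38%	1%	102
F53B7.3	40%	3%	14%	40%	3%	91
M03F8.3	69%	1%	4%	20%	6%	108
T11G6.8	64%	0%	3%	31%	2%	104
Y49E10.15	83%	1%	3%	11%	2%	100
Y57A10A.19	92%	1%	2%	4%	1%	104
Y66D12A.8	91%	1%	3%	0%	5%	102
K06A5.7	91%	2%	2%	1%	5%	108
ubl-1	NA	NA	NA	NA	NA	NA
Y37E3.8	NA	NA	NA	NA	NA	NA
eftu-2	NA	NA	NA	NA	NA	NA
prp-8	NA	NA	NA	NA	NA	NA
skp-1	NA	NA	NA	NA	NA	NA
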
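onset	duration	cross_duration	stim_type	trigger	button_pushed	response_time	stim_file
0	0.908	0.534	FAMOUS	5	4	2.158	func/f013.bmp
3.273	0.962	0.586	FAMOUS	6	4	1.233	func/f013.bmp
6.647	0.825	0.546	UNFAMILIAR	13	4	1.183	func/u014.bmp
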
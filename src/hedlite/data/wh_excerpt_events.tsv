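onset	duration	sample	event_type	face_type	rep_status	rep_lag	value	stim_file
0.400	n/a	1	setup_left_sym	n/a	n/a	n/a	2	n/a
23.870	n/a	26275	show_face_initial	famous_face	first_show	n/a	7	f032.bmp
24.081	n/a	26488	left_press	n/a	n/a	n/a	256	n/a
24.750	n/a	27225	show_circle	n/a	n/a	n/a	0	circle.bmp
26.457	n/a	29095	show_cross	n/a	n/a	n/a	1	cross.bmp
26.940	n/a	29634	show_face	famous_face	immediate_repeat	1	8	f032.bmp
27.913	n/a	30701	show_circle	n/a	n/a	n/a	0	circle.bmp
27.990	n/a	30789	right_press	n/a	n/a	n/a	4096	n/a
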
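study_id	contrast_id	modality	space	x	y	z	n_patients	n_controls
study01	study01_c1	SPECT	MNI	6	40	10	11	40
study01	study01_c1	SPECT	MNI	-10	12	6	11	40
study02	study02_c1	task_fMRI	MNI	48	22	-2	7	7
study02	study02_c1	task_fMRI	MNI	-44	-60	36	7	7
study03	study03_c1	task_fMRI	MNI	-58	-34	-4	9	9
study03	study03_c1	task_fMRI	MNI	12	12	6	9	9
study03	study03_c1	task_fMRI	MNI	4	38	12	9	9
study04	study04_c1	PET	TAL	-42	-58	34	7	7
study04	study04_c1	PET	TAL	10	10	4	7	7
study05	study05_c1	task_fMRI	MNI	52	-54	-14	14	14
study05	study05_c1	task_fMRI	MNI	-4	42	8	14	14
study06	study06_c1	PET	MNI	-12	10	10	7	7
study07	study07_c1	PET	MNI	14	14	2	11	11
study07	study07_c1	PET	MNI	-50	-40	-8	11	11
study08	study08_c1	SPECT	TAL	-8	36	14	21	63
study09	study09_c1	SPECT	MNI	10	8	8	15	15
study09	study09_c1	SPECT	MNI	44	-62	40	15	15
study10	study10_c1	rs_fMRI	MNI	-46	-64	32	15	15
study10	study10_c1	rs_fMRI	MNI	-56	-30	-8	15	15
study11	study11_c1	rs_fMRI	MNI	2	36	16	15	15
study11	study11_c1	rs_fMRI	MNI	-12	14	8	15	15
study12	study12_c1	task_fMRI	MNI	-40	-12	54	8	13
study13	study13_c1	PET	MNI	8	34	18	18	18
study13	study13_c1	PET	MNI	-54	-52	-12	18	18
study14	study14_c1	task_fMRI	MNI	46	-58	36	18	17
study15	study15_c1	rs_fMRI	MNI	-6	38	6	21	33
study15	study15_c1	rs_fMRI	MNI	10	14	10	21	33
study16	study16_c1	rs_fMRI	MNI	-60	-36	-6	37	37
study16	study16_c1	rs_fMRI	MNI	4	40	14	37	37
study17	study17_c1	VBM	MNI	-14	12	10	65	287
study17	study17_c1	VBM	MNI	50	-56	-10	65	287
study18	study18_c1	VBM	MNI	-48	-62	34	36	36
study18	study18_c1	VBM	MNI	6	12	4	36	36
study19	study19_c1	rs_fMRI	TAL	-52	-36	-6	10	10
study19	study19_c1	rs_fMRI	TAL	8	38	12	10	10
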
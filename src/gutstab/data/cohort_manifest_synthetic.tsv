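# synthetic cohort manifest: study-scale bookkeeping stand-in
isolate_id	subject_id	trial	timepoint	genome_size	gc_percent	ani_vs_reference
T1-A01	volunteer_A	1	d1	3171049	44.5	99.96
T1-A02	volunteer_A	1	d1	3204635	44.5	99.97
T1-A03	volunteer_A	1	d2	3181543	44.5	99.91
T1-A04	volunteer_A	1	d2	3199668	44.6	99.96
T1-A05	volunteer_A	1	d3	3175817	44.5	99.93
T1-A06	volunteer_A	1	d3	3195665	44.6	99.93
T1-A07	volunteer_A	1	d4	3211874	44.4	99.92
T1-A08	volunteer_A	1	d4	3216271	44.4	99.98
T1-A09	volunteer_A	1	d5	3224698	44.4	99.94
T1-A10	volunteer_A	1	d5	3190919	44.6	99.96
T1-A11	volunteer_A	1	d6	3170349	44.6	99.95
T1-A12	volunteer_A	1	d6	3197296	44.4	99.94
T1-A13	volunteer_A	1	d7	3218035	44.6	99.92
T1-A14	volunteer_A	1	d7	3178130	44.5	99.94
T1-A15	volunteer_A	1	d14	3170970	44.5	99.93
T1-A16	volunteer_A	1	d14	3217530	44.5	99.96
T1-B01	volunteer_B	1	d1	3203894	44.5	99.94
T1-B02	volunteer_B	1	d1	3198894	44.4	99.93
T1-B03	volunteer_B	1	d2	3176398	44.4	99.98
T1-B04	volunteer_B	1	d2	3200562	44.4	99.97
T1-B05	volunteer_B	1	d3	3180938	44.4	99.99
T1-B06	volunteer_B	1	d3	3226847	44.4	99.94
T1-B07	volunteer_B	1	d4	3194874	44.5	99.95
T1-B08	volunteer_B	1	d4	3175753	44.5	99.93
T1-B09	volunteer_B	1	d5	3183413	44.5	99.98
T1-B10	volunteer_B	1	d5	3190750	44.6	99.96
T1-B11	volunteer_B	1	d6	3174521	44.6	99.97
T1-B12	volunteer_B	1	d6	3227814	44.4	99.93
T1-B13	volunteer_B	1	d7	3192815	44.5	99.93
T1-B14	volunteer_B	1	d7	3188690	44.5	99.96
T1-B15	volunteer_B	1	d14	3204710	44.5	99.95
T1-B16	volunteer_B	1	d14	3227064	44.4	99.98
T1-C01	volunteer_C	1	d1	2024686	37.9	69.9
T1-C02	volunteer_C	1	d1	1989533	37.9	69.6
T1-C03	volunteer_C	1	d2	2019877	37.3	69.4
T1-C04	volunteer_C	1	d2	1995313	37.1	69.9
T1-C05	volunteer_C	1	d3	1976238	37.3	69.6
T1-C06	volunteer_C	1	d3	2033832	37.9	70.1
T1-C07	volunteer_C	1	d4	2017337	37.8	70.0
T1-C08	volunteer_C	1	d4	2031554	37.1	69.5
T1-C09	volunteer_C	1	d5	2014481	37.9	70.2
T1-C10	volunteer_C	1	d5	2042424	37.6	70.9
T1-C11	volunteer_C	1	d6	2040243	37.3	69.2
T1-C12	volunteer_C	1	d6	1998616	37.9	69.5
T1-C13	volunteer_C	1	d7	1969630	38.0	69.7
T1-C14	volunteer_C	1	d7	2047929	37.9	70.0
T1-C15	volunteer_C	1	d14	2023648	37.9	69.8
T1-C16	volunteer_C	1	d14	2025189	37.9	70.9
T2-R1-1	rat_1	2	d1	3222475	44.5	99.98
T2-R1-2	rat_1	2	d2	3216150	44.6	99.95
T2-R1-3	rat_1	2	d3	3208291	44.5	99.99
T2-R1-4	rat_1	2	d4	3224216	44.6	99.99
T2-R1-5	rat_1	2	d7	3221264	44.5	99.99
T2-R1-6	rat_1	2	d14	3195065	44.4	99.92
T2-R2-1	rat_2	2	d1	3170043	44.5	99.92
T2-R2-2	rat_2	2	d2	3174287	44.6	99.93
T2-R2-3	rat_2	2	d3	3209174	44.4	99.93
T2-R2-4	rat_2	2	d4	3197083	44.5	99.98
T2-R2-5	rat_2	2	d7	3203401	44.6	99.93
T2-R2-6	rat_2	2	d14	3203652	44.4	99.94
T2-R3-1	rat_3	2	d1	3178327	44.5	99.95
T2-R3-2	rat_3	2	d2	3191310	44.6	99.96
T2-R3-3	rat_3	2	d3	3185445	44.6	99.99
T2-R3-4	rat_3	2	d4	3203506	44.5	99.9
T2-R3-5	rat_3	2	d7	3182216	44.5	99.94
T2-R3-6	rat_3	2	d14	3176322	44.4	99.97
T2-R4-1	rat_4	2	d1	3193371	44.4	99.92
T2-R4-2	rat_4	2	d2	3183989	44.4	99.93
T2-R4-3	rat_4	2	d3	3186669	44.6	99.95
T2-R4-4	rat_4	2	d4	3229037	44.4	99.99
T2-R4-5	rat_4	2	d7	3174064	44.5	99.93
T2-R4-6	rat_4	2	d14	3172934	44.5	99.96
T2-R5-1	rat_5	2	d1	3180290	44.4	99.93
T2-R5-2	rat_5	2	d2	3171482	44.5	99.93
T2-R5-3	rat_5	2	d3	3179508	44.4	99.94
T2-R5-4	rat_5	2	d4	3223925	44.5	99.92
T2-R5-5	rat_5	2	d7	3223930	44.6	99.97
T2-R5-6	rat_5	2	d14	3205845	44.4	99.94
T2-R6-1	rat_6	2	d1	3217398	44.4	99.97
T2-R6-2	rat_6	2	d2	3201575	44.5	99.98
T2-R6-3	rat_6	2	d3	3192581	44.4	99.95
T2-R6-4	rat_6	2	d4	3179676	44.6	99.95
T2-R6-5	rat_6	2	d7	3221062	44.5	99.98
T2-R6-6	rat_6	2	d14	3188323	44.4	99.96
T2-R7-1	rat_7	2	d1	3203913	44.6	99.95
T2-R7-2	rat_7	2	d2	3197579	44.5	99.95
T2-R7-3	rat_7	2	d3	3215204	44.6	99.98
T2-R7-4	rat_7	2	d4	3216402	44.4	99.93
T2-R7-5	rat_7	2	d7	3212858	44.6	99.95
T2-R7-6	rat_7	2	d14	3212164	44.4	99.97
T2-R8-1	rat_8	2	d1	3186601	44.5	99.93
T2-R8-2	rat_8	2	d2	3206599	44.5	99.91
T2-R8-3	rat_8	2	d3	3229153	44.5	99.98
T3-01	volunteer_T3	3	w1	3200910	44.6	99.97
T3-02	volunteer_T3	3	w2	3170529	44.5	99.95
T3-03	volunteer_T3	3	w3	3221992	44.5	99.91
T3-04	volunteer_T3	3	w4	3197661	44.6	99.9
T3-05	volunteer_T3	3	w5	3229594	44.4	99.94
T3-06	volunteer_T3	3	w6	3176488	44.6	99.98
T3-07	volunteer_T3	3	w7	3196322	44.4	99.93
T3-08	volunteer_T3	3	w8	3200348	44.4	99.91
T3-09	volunteer_T3	3	w9	3215718	44.5	99.97
T3-10	volunteer_T3	3	w10	3186483	44.6	99.92
T3-11	volunteer_T3	3	w11	3227804	44.5	99.94
T3-12	volunteer_T3	3	w12	3180478	44.6	99.94
T3-13	volunteer_T3	3	w13	3185628	44.4	99.99
T3-14	volunteer_T3	3	w14	3228283	44.4	99.93
T3-15	volunteer_T3	3	w15	3200995	44.5	99.94
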
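	B1	B3	B4	B5	B6	B7	B8	B9	B10	B12	B13	B14	B15	B16
T1	0.52	0.19	0.38	0.17	0.11	0.23	0.27	0.16	0.17	0.07	0.13	0.10	0.28	0.12
T3	0.38	0.36	0.54	0.23	0.17	0.25	0.24	0.20	0.12	0.07	0.16	0.08	0.22	0.11
T4	0.33	0.19	0.69	0.17	0.28	0.14	0.18	0.16	0.09	0.05	0.13	0.05	0.17	0.08
T5	0.24	0.17	0.31	0.35	0.19	0.18	0.15	0.18	0.10	0.07	0.14	0.05	0.17	0.10
T6	0.19	0.10	0.23	0.15	0.25	0.07	0.09	0.10	0.07	0.05	0.13	0.08	0.11	0.06
T7	0.33	0.19	0.38	0.23	0.11	0.39	0.27	0.12	0.16	0.04	0.13	0.04	0.11	0.06
T8	0.19	0.07	0.15	0.10	0.06	0.18	0.48	0.10	0.16	0.09	0.13	0.03	0.06	0.11
T9	0.29	0.19	0.38	0.21	0.11	0.18	0.21	0.30	0.14	0.03	0.08	0.03	0.11	0.04
T10	0.33	0.14	0.38	0.13	0.08	0.25	0.48	0.18	0.33	0.09	0.21	0.04	0.06	0.06
T12	0.48	0.29	0.46	0.35	0.25	0.34	0.27	0.38	0.22	0.24	0.33	0.06	0.17	0.18
T13	0.52	0.33	0.46	0.35	0.22	0.30	0.24	0.32	0.25	0.18	0.45	0.12	0.33	0.23
T14	0.29	0.17	0.23	0.31	0.17	0.25	0.21	0.28	0.13	0.08	0.14	0.32	0.11	0.12
T15	0.24	0.21	0.23	0.19	0.22	0.23	0.18	0.34	0.13	0.12	0.18	0.03	0.28	0.20
T16	0.43	0.33	0.54	0.21	0.19	0.27	0.24	0.40	0.19	0.14	0.25	0.10	0.39	0.29
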
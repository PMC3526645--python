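	B1	B3	B4	B5	B6	B7	B8	B9	B10	B12	B13	B14	B15	B16
T1	0.29	0.13	0.10	0.14	0.07	0.13	0.07	0.09	0.07	0.08	0.11	0.03	0.15	0.14
T3	0.14	0.20	0.05	0.19	0.11	0.09	0.12	0.09	0.05	0.06	0.06	0.01	0.04	0.16
T4	0.05	0.05	0.28	0.08	0.15	0.04	0.05	0.06	0.05	0.03	0.05	0.01	0.08	0.05
T5	0.14	0.09	0.08	0.38	0.30	0.09	0.12	0.14	0.08	0.04	0.12	0.02	0.15	0.09
T6	0.19	0.13	0.05	0.16	0.30	0.16	0.17	0.14	0.08	0.01	0.02	0	0	0
T7	0.14	0.05	0.03	0.19	0.19	0.27	0.07	0.11	0.06	0.03	0.11	0.01	0.15	0.07
T8	0.05	0.11	0.10	0.03	0.07	0	0.31	0.09	0.06	0.03	0.06	0.01	0.04	0.05
T9	0.19	0.16	0.08	0.19	0.15	0.13	0.17	0.38	0.09	0.01	0.09	0	0.12	0.09
T10	0.33	0.14	0.05	0.19	0.26	0.13	0.17	0.11	0.36	0.06	0.09	0.03	0.04	0.07
T12	0.19	0.20	0.10	0.16	0.15	0.07	0.26	0.18	0.06	0.35	0.18	0.05	0.12	0.26
T13	0.33	0.30	0.18	0.43	0.30	0.20	0.29	0.40	0.17	0.20	0.52	0.06	0.19	0.26
T14	0.24	0.16	0.10	0.30	0.15	0.09	0.19	0.17	0.10	0.10	0.14	0.21	0.12	0.12
T15	0.29	0.25	0.10	0.41	0.37	0.18	0.29	0.14	0.14	0.15	0.23	0.07	0.31	0.16
T16	0.33	0.21	0.15	0.30	0.33	0.16	0.31	0.23	0.14	0.20	0.27	0.08	0.19	0.40
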
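	B1	B3	B4	B5	B6	B7	B8	B9	B10	B12	B13	B14	B15	B16
T1	0.21	0	0	0.02	0.03	0.04	0	0	0.07	0	0.01	0	0.02	0.02
T3	0	0.41	0	0.02	0.02	0.02	0.13	0	0	0.03	0	0.03	0.02	0.01
T4	0	0.03	0.37	0.06	0	0	0	0	0	0	0	0	0	0
T5	0	0	0.04	0.31	0.02	0	0	0	0.02	0	0	0.04	0.02	0.01
T6	0	0.03	0	0	0.27	0	0.07	0.05	0	0.01	0.02	0.09	0.02	0.03
T7	0.02	0	0	0.02	0.02	0.20	0.07	0	0.07	0	0	0.03	0.02	0.01
T8	0.02	0.03	0	0	0.02	0.02	0.27	0	0	0	0	0	0	0.01
T9	0	0	0.02	0	0.03	0	0	0.39	0.02	0.01	0	0.01	0	0.03
T10	0.03	0.08	0	0.02	0.05	0	0	0	0.38	0.01	0.01	0.01	0.02	0.01
T12	0	0	0	0	0	0.02	0	0	0.04	0.27	0	0.03	0.05	0.01
T13	0	0	0.04	0.03	0.03	0	0.07	0.03	0.02	0	0.22	0.01	0.06	0.02
T14	0	0	0.09	0.03	0	0	0	0.08	0.02	0.01	0.03	0.16	0.02	0.05
T15	0	0.03	0.04	0.05	0	0.02	0.07	0	0	0.02	0.02	0.15	0.15	0.01
T16	0	0.08	0.02	0.02	0.02	0	0	0.16	0.02	0.01	0.04	0.06	0.03	0.16
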
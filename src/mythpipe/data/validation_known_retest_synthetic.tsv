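# Synthetic per-row transcription of the known-interaction retest:
# 50 previously reported bait-prey pairs retested in the two-hybrid
# assay, 12 confirmed (24%). Per-row membership is a synthetic stand-in.
bait_id	prey_id	method	outcome
B01	K01	myth_retest	validated
B02	K02	myth_retest	validated
B03	K03	myth_retest	validated
B04	K04	myth_retest	validated
B05	K05	myth_retest	validated
B06	K06	myth_retest	validated
B07	K07	myth_retest	validated
B08	K08	myth_retest	validated
B09	K09	myth_retest	validated
B10	K10	myth_retest	validated
B01	K11	myth_retest	validated
B02	K12	myth_retest	validated
B03	K13	myth_retest	not_validated
B04	K14	myth_retest	not_validated
B05	K15	myth_retest	not_validated
B06	K16	myth_retest	not_validated
B07	K17	myth_retest	not_validated
B08	K18	myth_retest	not_validated
B09	K19	myth_retest	not_validated
B10	K20	myth_retest	not_validated
B01	K21	myth_retest	not_validated
B02	K22	myth_retest	not_validated
B03	K23	myth_retest	not_validated
B04	K24	myth_retest	not_validated
B05	K25	myth_retest	not_validated
B06	K26	myth_retest	not_validated
B07	K27	myth_retest	not_validated
B08	K28	myth_retest	not_validated
B09	K29	myth_retest	not_validated
B10	K30	myth_retest	not_validated
B01	K31	myth_retest	not_validated
B02	K32	myth_retest	not_validated
B03	K33	myth_retest	not_validated
B04	K34	myth_retest	not_validated
B05	K35	myth_retest	not_validated
B06	K36	myth_retest	not_validated
B07	K37	myth_retest	not_validated
B08	K38	myth_retest	not_validated
B09	K39	myth_retest	not_validated
B10	K40	myth_retest	not_validated
B01	K41	myth_retest	not_validated
B02	K42	myth_retest	not_validated
B03	K43	myth_retest	not_validated
B04	K44	myth_retest	not_validated
B05	K45	myth_retest	not_validated
B06	K46	myth_retest	not_validated
B07	K47	myth_retest	not_validated
B08	K48	myth_retest	not_validated
B09	K49	myth_retest	not_validated
B10	K50	myth_retest	not_validated
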
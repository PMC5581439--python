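# family	substrate_class (reporting aid; edit freely)
GH1	other
GH2	other
GH3	other
GH4	other
GH5	cellulolytic
GH6	cellulolytic
GH7	other
GH8	cellulolytic
GH9	cellulolytic
GH10	other
GH11	other
GH12	cellulolytic
GH13	starch
GH14	starch
GH15	starch
GH16	other
GH17	other
GH18	chitin
GH19	chitin
GH20	chitin
GH21	other
GH22	other
GH23	chitin
GH24	other
GH25	other
GH26	other
GH27	other
GH28	other
GH29	other
GH30	other
GH31	starch
GH32	other
GH33	other
GH34	other
GH35	other
GH36	other
GH37	other
GH38	other
GH39	other
GH40	other
GH41	other
GH42	other
GH43	other
GH44	cellulolytic
GH45	cellulolytic
GH46	chitin
GH47	other
GH48	cellulolytic
GH49	other
GH50	other
GH51	cellulolytic
GH52	other
GH53	other
GH54	other
GH55	other
GH56	other
GH57	starch
GH58	other
GH59	other
GH60	other
GH61	other
GH62	other
GH63	other
GH64	other
GH65	other
GH66	other
GH67	other
GH68	other
GH69	other
GH70	other
GH71	other
GH72	other
GH73	chitin
GH74	cellulolytic
GH75	other
GH76	other
GH77	starch
GH78	other
GH79	other
GH80	other
GH81	other
GH82	other
GH83	other
GH84	chitin
GH85	chitin
GH86	other
GH87	other
GH88	other
GH89	other
GH90	other
GH91	other
GH92	other
GH93	other
GH94	other
GH95	other
GH96	other
GH97	starch
GH98	other
GH99	other
GH100	other
GH101	other
GH102	other
GH103	other
GH104	other
GH105	other
GH106	other
GH107	other
GH108	other
GH109	other
GH110	other
GH111	other
GH112	other
GH113	other
GH114	other
GH115	other
GH116	other
GH117	other
GH118	other
GH119	starch
GH120	other
GH121	other
GH122	other
GH123	other
GH124	other
GH125	other
GH126	other
GH127	other
GH128	other
GH129	other
GH130	other
GH131	other
GH132	other
GH133	starch
GH134	other
GH135	other
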
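position	assay_cat_no	mirna_id	target_sequence	role
1	YP00205943	miR-20b	CAAAGUGCUCACAGUGCAGGUA	target
2	YP02113807	miR-10a	UACCCUGUAGAUCCGAAUUUGU	target
3	YP02110018	miR-141	AACACUGUCUGGUAAAGAUGG	target
4	YP02102101	miR-142	CCCAUAAAGUAGAAAGCACUA	target
5	YP02100678	miR-188	CAUCCCUUGCAUGGUGGAGGGU	target
6	YP02113947	miR-196b	UAGGUAGUUUCCUGUUGUUGGGA	target
7	YP02104713	miR-221	AGCUACAUUGUCUGCUGGGUUU	target
8	YP02116318	miR-32	UAUUGCACAUUACUAAGUUGCAU	target
9	YP02114619	miR-411	AUAGUAGACCGUAUAGCGUACG	target
10	YP02115385	miR-503	UAGCAGCGGGAACAGUACUG	target
11	YP02102538	miR-18a	UAAGGUGCAUCUAGUGCAGAUA	target
12	YP02100265	miR-18b	UAAGGUGCAUCUAGUGCAGUUA	target
13	YP00204130	miR-135b	UAUGGCUUUUCAUUCCUAUGUGA	target
14	YP00204688	miR-146a	UGAGAACUGAAUUCCAUGGGUU	target
15	YP00204660	miR-150	UCUCCCAACCCUUGUACCAGUG	target
16	YP00204018	miR-187	UCGUGUCUUGUGUUGCAGCCGG	target
17	YP00204665	miR-193a	UGGGUCUUUGCGGGCGAGAUGA	target
18	YP00204482	miR-200c	UAAUACUGCCGGGUAAUGAUGGA	target
19	YP00205616	miR-202	UUCCUAUGCAUAUACUUCUUUG	target
20	YP00205914	miR-203a	GUGAAAUGUUUAGGACCACUAG	target
21	YP00204487	miR-205	UCCUUCAUUCCACCGGAGUCUG	target
22	YP00205401	miR-212	ACCUUGGCUCUAGACUGCUUACU	target
23	YP00204364	miR-328	CUGGCCCUCUCUGCCCUUCCGU	target
24	YP02119293	miR-335	UCAAGAGCAAUAACGAAAAAUGU	target
25	YP00204486	miR-34a	UGGCAGUGUCUUAGCUGGUUGU	target
26	YP00205659	miR-34c	AGGCAGUGUAGUUAGCUGAUUGC	target
27	YP00204618	miR-362	AAUCCUUGGAACCUAGGUGUGAGU	target
28	YP00204011	miR-370	GCCUGCUGGGGUGGAACCUGGU	target
29	YP00204362	miR-375	UUUGUUCGUUCGGCUCGCGUGA	target
30	YP00204218	miR-376b	AUCAUAGAGGAAAAUCCAUGUU	target
31	YP00204301	miR-452	AACUGUUUGCAGAGGAAACUGA	target
32	YP00204489	miR-487b	AAUCGUACAGGGUCAUCCACUU	target
33	YP00204579	miR-494	UGAAACAUACACGGGAAACCUC	target
34	YP00205657	miR-505	GGGAGCCAGGAAGUAUUGAUGU	target
35	YP00204447	miR-543	AAACAUUCGCGGUGCACUUCUU	target
36	YP00205983	miR-99b	CACCCGUAGAACCGACCUUGCG	target
37	YP00205427	miR-376c	GUGGAUAUUCCUUCUAUGUUUA	target
38	YP02119694	miR-7a	UGGAAGACUAGUGAUUUUGUUGU	target
39	YP00205120	miR-223	UGUCAGUUUGUCAAAUACCCC	target
40	YP00205141	miR-493	UGAAGGUCUACUGUGUGCCAG	target
41	YP00203907	U6 snRNA		control
42	YP02119288	UniSP3		control
43	YP00203954	UniSp6		control
44	YP02121094	miR-8859a	UGGAUCGGAGCCGGGGUCCGGA	reference
45	YP02121097	miR-8859b	GGUCGGAUUCCGUGCCUGGAGU	reference
46	YP02121124	miR-8884	UUUGAUGGAUUUGCUUAGCACC	reference
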
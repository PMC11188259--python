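rsid	H01	H02	H03	H04	H05	H06	H07	H08	H10	H11	H12	H13	H14	H15	H16	H17
rs740623580	G	G	G	G	A	G	G	G	G	G	G	G	G	G	G	G
rs869007872	C	T	T	C	C	C	C	T	C	C	T	T	C	T	C	T
rs794503708	C	T	T	C	C	C	C	T	C	C	T	T	C	T	C	T
rs733753324	G	C	G	G	G	G	G	G	G	G	C	G	G	C	G	G
rs731472668	A	G	A	A	A	A	A	G	A	A	G	A	G	G	A	A
rs738943348	T	C	T	T	T	T	T	C	T	T	C	T	C	C	T	T
rs739602946	T	C	T	T	T	T	T	C	T	T	C	T	C	C	T	T
rs738898886	A	G	A	A	A	A	-	G	A	A	-	-	A	G	-	A
rs313465722	T	C	T	T	T	T	-	C	T	T	-	-	T	C	-	T
rs735870559	G	G	G	G	G	G	-	T	G	G	-	-	G	T	-	G
rs316593393	A	A	G	G	G	G	-	G	G	A	-	-	G	G	-	G
rs733511284	T	T	G	G	G	G	-	G	G	T	-	-	G	G	-	G
rs314800215	G	A	G	G	G	A	-	G	G	A	-	-	G	G	-	G
rs738163839	C	A	C	C	C	A	-	C	C	A	-	-	C	C	-	C
rs737604974	G	A	G	G	G	A	-	G	A	G	-	-	G	G	-	A
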
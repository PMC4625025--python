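name	scaffold	strand	gene_len	cds_len	intron_count
RcPIP1;1	29969	+	1370	867	3
RcPIP1;2	29669	-	1304	864	3
RcPIP1;3	29669	-	1243	867	3
RcPIP1;4	30190	+	2648	864	3
RcPIP1;5	30174	+	1712	861	3
RcPIP2;1	30078	+	1185	867	3
RcPIP2;2	27516	+	2665	852	3
RcPIP2;3	28076	+	1939	864	3
RcPIP2;4	29869	-	1221	843	3
RcPIP2;5	28962	-	1654	813	4
RcTIP1;1	30078	+	871	756	1
RcTIP1;2	28180	+	1149	759	2
RcTIP1;3	29788	+	1070	759	2
RcTIP1;4	29589	-	1129	759	1
RcTIP2;1	30146	-	1300	747	2
RcTIP2;2	30101	+	1059	753	2
RcTIP3;1	29681	+	994	768	2
RcTIP4;1	29794	-	1017	744	2
RcTIP5;1	30147	+	1241	759	2
RcNIP1;1	30026	+	2079	816	4
RcNIP2;1	27860	+	2598	894	4
RcNIP3;1	29908	-	1310	849	4
RcNIP4;1	29816	-	1425	810	4
RcNIP4;2	28827	+	3018	759	4
RcNIP5;1	30068	+	4934	897	3
RcNIP6;1	29588	+	3320	927	4
RcNIP7;1	29844	+	1258	897	4
RcXIP1;1	28929	-	1195	930	1
RcXIP1;2	28846	-	1346	912	1
RcXIP1;3	28846	-	858	858	0
RcXIP1;4	28929	-	727	627	1
RcXIP2;1	28747	-	1302	921	2
RcXIP3;1	28747	-	1827	915	1
RcSIP1;1	29950	-	4822	720	2
RcSIP1;2	30010	-	705	705	0
RcSIP1;3	30010	-	720	720	0
RcSIP2;1	30045	-	3962	723	2
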
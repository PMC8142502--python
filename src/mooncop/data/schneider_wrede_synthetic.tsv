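	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0	0.133761	0.584468	0.632383	0.602849	0.234236	0.514886	0.49459	0.7353	0.475346	0.414574	0.430421	0.293521	0.506027	0.777741	0.217016	0.240695	0.352672	0.853575	0.651494
C	0.133761	0	0.650333	0.670181	0.476411	0.361341	0.496752	0.362618	0.746707	0.344074	0.301149	0.474162	0.330976	0.5106	0.787978	0.309989	0.254395	0.221632	0.751445	0.564739
D	0.584468	0.650333	0	0.148377	0.906472	0.504239	0.469204	0.87695	0.313965	0.841594	0.70512	0.32761	0.378761	0.372356	0.346881	0.394129	0.450644	0.798482	1	0.782375
E	0.632383	0.670181	0.148377	0	0.84653	0.598774	0.417452	0.837485	0.166881	0.800388	0.660048	0.352853	0.403602	0.328518	0.204597	0.461517	0.465866	0.782929	0.913122	0.707858
F	0.602849	0.476411	0.906472	0.84653	0	0.800709	0.546488	0.197451	0.825329	0.16812	0.213997	0.703172	0.609293	0.622498	0.850567	0.693779	0.539081	0.313577	0.36216	0.310353
G	0.234236	0.361341	0.504239	0.598774	0.800709	0	0.551302	0.718429	0.734951	0.692821	0.604371	0.375773	0.299833	0.511874	0.772964	0.163734	0.30876	0.582543	0.995009	0.776727
H	0.514886	0.496752	0.469204	0.417452	0.546488	0.551302	0	0.604013	0.420798	0.553583	0.39885	0.22883	0.257664	0.099056	0.434657	0.403944	0.276141	0.573997	0.556105	0.336065
I	0.49459	0.362618	0.87695	0.837485	0.197451	0.718429	0.604013	0	0.845604	0.052725	0.205407	0.706714	0.584369	0.658184	0.880622	0.630814	0.505771	0.150991	0.557379	0.46437
K	0.7353	0.746707	0.313965	0.166881	0.825329	0.734951	0.420798	0.845604	0	0.806913	0.666564	0.442393	0.495199	0.35516	0.052182	0.584159	0.545323	0.820317	0.844946	0.663633
L	0.475346	0.344074	0.841594	0.800388	0.16812	0.692821	0.553583	0.052725	0.806913	0	0.155952	0.662332	0.543891	0.610282	0.840709	0.598841	0.466136	0.152301	0.520155	0.415153
M	0.414574	0.301149	0.70512	0.660048	0.213997	0.604371	0.39885	0.205407	0.666564	0.155952	0	0.516243	0.408679	0.454902	0.698665	0.487485	0.337805	0.21459	0.478669	0.315581
N	0.430421	0.474162	0.32761	0.352853	0.703172	0.375773	0.22883	0.706714	0.442393	0.662332	0.516243	0	0.145206	0.161422	0.465417	0.245164	0.222515	0.629008	0.772797	0.547274
P	0.293521	0.330976	0.378761	0.403602	0.609293	0.299833	0.257664	0.584369	0.495199	0.543891	0.408679	0.145206	0	0.222707	0.528636	0.146466	0.084391	0.49355	0.742959	0.515833
Q	0.506027	0.5106	0.372356	0.328518	0.622498	0.511874	0.099056	0.658184	0.35516	0.610282	0.454902	0.161422	0.222707	0	0.372314	0.360839	0.268441	0.613402	0.650973	0.431357
R	0.777741	0.787978	0.346881	0.204597	0.850567	0.772964	0.434657	0.880622	0.052182	0.840709	0.698665	0.465417	0.528636	0.372314	0	0.62261	0.580322	0.859592	0.8487	0.673605
S	0.217016	0.309989	0.394129	0.461517	0.693779	0.163734	0.403944	0.630814	0.584159	0.598841	0.487485	0.245164	0.146466	0.360839	0.62261	0	0.168649	0.512749	0.869544	0.645704
T	0.240695	0.254395	0.450644	0.465866	0.539081	0.30876	0.276141	0.505771	0.545323	0.466136	0.337805	0.222515	0.084391	0.268441	0.580322	0.168649	0	0.411841	0.701211	0.478294
V	0.352672	0.221632	0.798482	0.782929	0.313577	0.582543	0.573997	0.150991	0.820317	0.152301	0.21459	0.629008	0.49355	0.613402	0.859592	0.512749	0.411841	0	0.651597	0.514999
W	0.853575	0.751445	1	0.913122	0.36216	0.995009	0.556105	0.557379	0.844946	0.520155	0.478669	0.772797	0.742959	0.650973	0.8487	0.869544	0.701211	0.651597	0	0.227997
Y	0.651494	0.564739	0.782375	0.707858	0.310353	0.776727	0.336065	0.46437	0.663633	0.415153	0.315581	0.547274	0.515833	0.431357	0.673605	0.645704	0.478294	0.514999	0.227997	0
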
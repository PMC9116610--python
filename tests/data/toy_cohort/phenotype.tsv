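sample	status
S00001	affected
S00002	affected
S00003	affected
S00004	affected
S00005	affected
S00006	affected
S00007	affected
S00008	affected
S00009	affected
S00010	affected
S00011	affected
S00012	affected
S00013	affected
S00014	affected
S00015	affected
S00016	affected
S00017	affected
S00018	affected
S00019	affected
S00020	affected
S00021	affected
S00022	affected
S00023	affected
S00024	affected
S00025	affected
S00026	affected
S00027	affected
S00028	affected
S00029	affected
S00030	affected
S00031	affected
S00032	affected
S00033	affected
S00034	affected
S00035	affected
S00036	affected
S00037	affected
S00038	affected
S00039	affected
S00040	affected
S00041	affected
S00042	affected
S00043	affected
S00044	affected
S00045	affected
S00046	affected
S00047	affected
S00048	affected
S00049	affected
S00050	affected
S00051	affected
S00052	affected
S00053	affected
S00054	affected
S00055	affected
S00056	affected
S00057	affected
S00058	affected
S00059	affected
S00060	affected
S00061	affected
S00062	affected
S00063	affected
S00064	affected
S00065	affected
S00066	affected
S00067	affected
S00068	affected
S00069	affected
S00070	affected
S00071	affected
S00072	affected
S00073	affected
S00074	affected
S00075	affected
S00076	affected
S00077	affected
S00078	affected
S00079	affected
S00080	affected
S00081	unaffected
S00082	unaffected
S00083	unaffected
S00084	unaffected
S00085	unaffected
S00086	unaffected
S00087	unaffected
S00088	unaffected
S00089	unaffected
S00090	unaffected
S00091	unaffected
S00092	unaffected
S00093	unaffected
S00094	unaffected
S00095	unaffected
S00096	unaffected
S00097	unaffected
S00098	unaffected
S00099	unaffected
S00100	unaffected
S00101	unaffected
S00102	unaffected
S00103	unaffected
S00104	unaffected
S00105	unaffected
S00106	unaffected
S00107	unaffected
S00108	unaffected
S00109	unaffected
S00110	unaffected
S00111	unaffected
S00112	unaffected
S00113	unaffected
S00114	unaffected
S00115	unaffected
S00116	unaffected
S00117	unaffected
S00118	unaffected
S00119	unaffected
S00120	unaffected
S00121	unaffected
S00122	unaffected
S00123	unaffected
S00124	unaffected
S00125	unaffected
S00126	unaffected
S00127	unaffected
S00128	unaffected
S00129	unaffected
S00130	unaffected
S00131	unaffected
S00132	unaffected
S00133	unaffected
S00134	unaffected
S00135	unaffected
S00136	unaffected
S00137	unaffected
S00138	unaffected
S00139	unaffected
S00140	unaffected
S00141	unaffected
S00142	unaffected
S00143	unaffected
S00144	unaffected
S00145	unaffected
S00146	unaffected
S00147	unaffected
S00148	unaffected
S00149	unaffected
S00150	unaffected
S00151	unaffected
S00152	unaffected
S00153	unaffected
S00154	unaffected
S00155	unaffected
S00156	unaffected
S00157	unaffected
S00158	unaffected
S00159	unaffected
S00160	unaffected
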
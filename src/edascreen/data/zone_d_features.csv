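feature_id,neutral_mass,mz,rt_min,parent_area,formula,mass_error_ppm,active_endpoint,n_candidates,n_active_candidates,top_decile_active,insource_cluster,insource_evidence
1,139.0633,140.07058,9.71,3.9e7,C7H9NO2,-0.17,,2116,18,0,,
2,186.0528,187.06011,10.61,1.5e7,C8H10O5,0.05,,803,23,3,A,shared_fragments
3,214.0478,215.05504,10.61,9.0e7,C9H10O6,0.14,,293,6,0,A,shared_fragments
4,246.0740,247.08126,10.61,6.8e7,C10H14O7,0.08,,233,8,0,A,shared_fragments
5,232.0583,233.06561,10.61,2.0e7,C9H12O7,0.12,,151,4,0,A,shared_fragments
6,200.0321,201.03933,10.61,2.1e7,C8H8O6,-0.17,,293,8,1,A,shared_fragments
7,263.1005,264.10776,10.81,6.3e6,C10H17NO7,-0.08,TOX21_DT40_ratio,138,6,1,,
8,280.0503,281.05753,14.58,6.6e6,C14H13ClO4,0.05,,329,24,0,,
9,246.0892,247.09648,15.01,4.6e7,C14H14O4,-0.04,,2757,238,10,,
10,210.0529,211.06016,15.23,2.1e7,C10H10O5,0.21,,1283,41,1,,
11,150.0318,151.03905,15.23,1.4e7,C8H6O3,0.54,,311,10,6,,
12,405.1788,406.18602,15.39,3.0e7,C21H27NO7,-0.02,TOX21_p53_BLA,356,20,2,B,precursor_in_fragments
13,186.0681,187.07534,15.39,2.3e7,C12H10O2,-0.07,TOX21_DT40_ratio,1085,39,17,B,precursor_in_fragments
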
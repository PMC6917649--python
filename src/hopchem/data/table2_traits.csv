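site_code,subspecies,habitat,total_prenylchalcones,total_prenylchalcones_se,xga,mxh,total_alpha,total_alpha_se,prop_coh,total_beta,total_beta_se,alpha_ratio,malonyl_proportion
S-JS,lupuloides,farmstead,0.47,0.02,0.036,0.030,5.67,0.16,0.40,3.97,0.09,0.59,0.055
B-GC,lupuloides,forested,0.59,0.03,0.041,0.044,6.10,0.42,0.47,4.41,0.26,0.58,0.022
S-BA,lupuloides,farmstead,0.62,0.03,0.049,0.040,6.29,0.23,0.40,5.37,0.16,0.54,0.021
P-TG,lupuloides,farmstead,0.48,0.02,0.030,0.025,5.68,0.27,0.41,5.46,0.25,0.51,0.063
P-CB,lupuloides,fresh water marsh,0.58,0.01,0.038,0.033,6.28,0.17,0.41,5.58,0.12,0.53,0.028
P-CC,lupuloides,estuary,0.63,0.02,0.042,0.042,6.96,0.22,0.42,5.65,0.18,0.55,0.029
S-MD,lupuloides,farmstead,0.53,0.01,0.034,0.031,6.16,0.30,0.41,5.68,0.11,0.52,0.031
P-WR,lupuloides,riparian,0.74,0.04,0.048,0.045,7.74,0.51,0.42,5.72,0.39,0.58,0.058
P-CP,lupuloides,fresh water marsh,0.65,0.05,0.043,0.039,7.25,0.47,0.42,5.74,0.40,0.56,0.044
P-DU,lupuloides,forested,0.62,0.03,0.036,0.036,6.75,0.37,0.42,5.75,0.24,0.54,0.027
P-MV,lupuloides,riparian,0.54,0.03,0.046,0.040,6.22,0.36,0.40,5.82,0.21,0.52,0.028
P-MR,lupuloides,riparian,0.74,0.04,0.052,0.047,7.84,0.42,0.41,6.02,0.18,0.57,0.036
S-TR,lupuloides,farmstead,0.62,0.01,0.041,0.038,7.34,0.16,0.39,6.03,0.18,0.55,0.030
S-SC,lupuloides,roadside,0.72,0.04,0.048,0.045,7.96,0.32,0.39,6.30,0.27,0.56,0.028
B-TW,lupuloides,farmstead,0.81,0.03,0.062,0.057,9.38,0.18,0.40,6.34,0.12,0.60,0.026
P-WG,lupuloides,roadside,0.71,0.03,0.049,0.042,7.68,0.26,0.42,6.47,0.16,0.54,0.036
B-SG,lupuloides,estuary,0.69,0.03,0.040,0.041,8.99,0.32,0.40,6.98,0.26,0.56,0.035
B-FG,lupuloides,farmstead,0.88,0.02,0.098,0.074,2.53,0.05,0.39,9.93,0.19,0.20,0.028
S-AP,lupuloides,estuary,1.15,0.07,0.111,0.087,3.51,0.14,0.36,12.0,0.64,0.23,0.027
P-NW,lupulus,farmstead,0.52,0.02,0.000,0.000,6.07,0.23,0.26,2.12,0.09,0.74,0.324
P-HF,lupulus,old hopyard,0.58,0.01,0.000,0.000,5.95,0.17,0.32,2.55,0.04,0.70,0.221
B-DX,lupulus,farmstead,0.65,0.03,0.000,0.000,8.31,0.44,0.31,2.70,0.13,0.75,0.531
P-HR,lupulus,riparian,0.51,0.01,0.000,0.000,5.32,0.22,0.29,2.74,0.07,0.66,0.386
P-WB,lupulus,farmstead,0.60,0.03,0.000,0.000,5.21,0.35,0.33,3.85,0.20,0.57,0.511
S-MI,lupulus,riparian,0.29,0.03,0.000,0.000,1.70,0.13,0.19,4.15,0.37,0.29,0.388
S-89,lupulus,farmstead,0.38,0.02,0.000,0.000,2.16,0.10,0.18,4.98,0.24,0.30,0.383
P-WK,lupulus,farmstead,0.64,0.03,0.000,0.000,7.33,0.70,0.36,5.50,0.37,0.57,0.242
S-WM,lupulus,riparian,0.44,0.03,0.000,0.000,2.33,0.13,0.21,6.29,0.49,0.27,0.290
S-11,lupulus,roadside,0.51,0.03,0.000,0.000,2.94,0.16,0.18,6.54,0.35,0.31,0.536
S-81,lupulus,roadside,0.50,0.03,0.000,0.000,3.05,0.15,0.17,6.55,0.27,0.32,0.491
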
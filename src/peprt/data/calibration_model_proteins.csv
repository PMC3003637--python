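protein_label,peptide_sequence,mz,charge,xcorr,missed_cleavages,clogp,log_sum_k1,t_r_exp,t_r_pred,delta_t_r
BML,ALKALPMHIR,575.7332,2,3.06,1,-1.74,1.3542,25.12,25.13,0.01
BSA,LFTFHADICTLPDTEKQIK,1111.2810,2,3.21,1,-4.60,1.6674,32.60,32.62,0.02
COA,KIKVYLPR,509.1467,2,2.27,2,-0.95,1.3005,24.06,24.08,0.02
HSA,LVNEVTEFAK,575.6500,2,3.42,0,-2.44,1.3540,24.53,24.56,0.03
BML,YTRKVPQVSTPTLVEVSR,1031.1858,2,3.01,2,-5.67,1.4758,25.80,25.77,0.03
IGFBP-1,ALHVTNIK,896.0698,1,2.48,0,-3.14,1.2148,19.69,19.64,0.04
BSA,DTHKSEIAHR,597.6416,2,2.80,1,-7.77,1.1246,13.15,13.10,0.05
HSA,AAFTECCQAADK,687.7000,2,3.07,0,-5.69,1.2657,19.31,19.18,0.13
IGFBP-1,ALPGEQQPLHALTR,766.3710,2,3.37,0,-5.22,1.4145,24.36,24.21,0.15
BMC,VKEAMAPK,874.0844,1,2.13,1,-2.19,1.0165,14.40,14.21,0.19
RibB,QHMDSSTSAASSSNYCNQMMK,789.8418,3,4.75,0,-11.80,1.4546,20.46,20.18,0.28
BSA,AFDEKLFTFHADICTLPDTEK,814.9098,3,5.11,1,-4.51,1.7127,34.45,34.11,0.34
RibB,HIIVACEGNPYVPVHFDASV,1113.7305,2,5.15,0,-3.51,1.6128,32.15,31.79,0.36
HSA,VHTECCHGDLLECADDRADLAK,1295.3400,2,4.47,1,-9.95,1.5447,24.98,24.48,0.50
BSA,AFDEKLFTFHADICTLPDTEKQIK,1406.5952,2,4.42,2,-4.95,1.7629,34.77,35.32,0.55
HSA,DLGEENFK,952.0000,1,2.09,0,-4.48,1.2654,19.46,20.15,0.69
HSA,CCAAADPHECYAK,778.7900,2,3.46,0,-5.77,1.2195,16.98,17.68,0.70
IGFBP-1,IPGSPEIR,869.0012,1,2.18,0,-2.43,1.1657,19.40,18.68,0.72
BML,LKPDPNTLCDEFKADEKKFWGKYLYEIAR,1174.0045,3,4.49,5,-5.45,1.8691,39.20,38.24,0.96
IGFBP-1,ALHVTNIKK,1024.2427,1,2.01,1,-4.64,1.2405,18.27,19.24,0.97
BMC,VLPVPQKAVPYPQR,796.9551,2,3.32,1,-3.24,1.3948,24.20,25.19,0.99
HSA,AEFAEVSK,880.9700,1,2.10,0,-2.94,1.1909,18.06,19.06,1.00
IGFBP-1,ALHVTNIKK,512.6214,2,2.70,1,-4.64,1.2405,18.24,19.24,1.00
HSA,TCVADESAENCDK,751.2300,2,4.05,0,-7.23,1.1488,15.32,14.29,1.03
HSA,NECFLQHK,1077.1600,1,2.33,0,-3.74,1.2654,19.67,20.74,1.07
BSA,TCVADESHAGCEK,675.7310,2,3.47,0,-7.76,1.1488,14.99,13.87,1.12
BSA,CASIQKFGER,570.1555,2,2.78,1,-4.66,1.2958,19.81,20.95,1.14
HSA,VHTECCHGDLLECADDR,1046.0500,2,6.23,0,-8.42,1.4161,22.86,21.69,1.17
BSA,LFTFHADICTLPDTEK,926.5506,2,4.79,0,-3.25,1.6039,32.90,31.72,1.18
IGFBP-1,RIPGSPEIR,513.0938,2,2.63,1,-3.50,1.1944,20.00,18.72,1.29
BSA,HLVDEPQNLIK,653.7467,2,3.48,0,-4.68,1.3690,24.56,23.23,1.33
BSA,TCVADESHAGCEKSLHTLFGDELCK,1348.0020,2,3.77,1,-7.37,1.6483,31.14,29.79,1.35
RibB,YPNCAYK,916.9852,1,2.58,0,-2.34,1.1508,16.78,18.29,1.51
BML,LRCASIQKFGER,704.8278,2,3.82,2,-4.96,1.4107,22.79,24.31,1.51
IGFBP-1,WKEPCRIELYR,747.3795,2,2.70,2,-3.52,1.4991,26.67,28.23,1.56
BML,TPEVDDEALEKFDK,818.8696,2,5.09,1,-6.12,1.4067,24.94,23.25,1.69
HSA,LDELRDEGK,538.0800,2,2.52,1,-5.34,1.2299,16.62,18.35,1.73
HSA,YICENQDTISSKL,732.6700,2,3.80,1,-5.93,1.4238,22.69,23.93,1.24
BSA,YICDNQDTISSKLK,814.9150,2,4.03,1,-6.10,1.4504,22.75,24.63,1.88
BSA,QTALVELLKHKPK,753.4154,2,2.89,2,-3.08,1.4159,27.89,25.98,1.91
BMC,VKEAMAPKHK,570.1986,2,2.90,2,-3.41,1.0930,13.48,15.62,2.14
COA,ELINSWVESQTNGIIR,930.5307,2,3.93,0,-5.86,1.6097,31.95,29.80,2.15
COA,ISQAVHAAHAEINEAGR,887.9599,2,3.19,0,-7.56,1.3932,19.51,21.67,2.16
BSA,YICDNQDTISSK,694.2494,2,3.80,0,-6.61,1.3468,18.79,20.98,2.19
BML,SHCIAEVEKDAIPENLPPLTADFAEDKDVCK,1133.9316,3,5.65,2,-3.53,1.7342,33.13,35.57,2.44
COA,GGLEPINFQTAADQAR,844.9119,2,4.19,0,-6.71,1.4735,27.41,24.86,2.55
BMC,EAMAPKHKEMPFPK,821.4917,2,3.87,2,-3.31,1.3625,21.52,24.12,2.60
IGFBP-1,FYLPNCNKNGFYHSR,931.0381,2,2.76,0,-5.83,1.5912,26.57,29.25,2.68
HSA,YICENQDSISSK,723.2500,2,4.04,0,-6.77,1.3468,18.06,20.85,2.79
BSA,SLHTLFGDELCK,682.2826,2,3.55,0,-3.32,1.4829,30.69,27.88,2.81
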
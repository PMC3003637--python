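protein_label,peptide_sequence,mz,charge,xcorr,missed_cleavages,clogp,log_sum_k1,t_r_exp,t_r_pred,delta_t_r,printed_group
SASP - alpha-type,LVSFAQQNMGGGQF,742.8313,2,4.72,0,-0.78,1.5218,28.39,30.85,-2.46,CORRECT
SASP - alpha-type,RLVSFAQQNMGGGQF,820.9245,2,3.69,1,-1.13,1.5346,30.98,30.99,-0.01,CORRECT
SASP - alpha-type,ANNNSGNSNNLLVPGAAQAIDQMK,814.8842,3,3.41,0,-1.15,1.5762,31.02,32.32,-1.30,CORRECT
SASP - alpha-type,ANGSVGGEITKRLVSFAQQNMGGGQF,1327.9721,2,3.84,2,-0.68,1.696,39.28,36.53,2.75,CORRECT
SASP - beta-type S,ANQNSSNDLLVPGAAQAIDQMK,1143.7547,2,3.25,0,-1.18,1.5526,31.64,31.54,0.10,CORRECT
SASP - beta-type S,LEIASEFGVNLGADTTSR,941.0171,2,4.30,0,-1.25,1.5661,33.14,31.92,1.22,CORRECT
SASP - B. subtilis,NVIQGALEDAGSALKDDPLQEAVQK,1305.9299,2,4.23,1,-1.01,1.628,37.99,34.09,3.90,CORRECT
SASP - B. subtilis,NVIQGALEDAGSALKDDPLQEAVQK,870.9532,3,3.80,1,-1.01,1.628,37.95,34.09,3.86,CORRECT
SASP - alpha/beta-type,GRRRGV,700.8170,1,0.69,3,-2.48,0.8503,91.69,7.95,83.74,INCORRECT
SASP - alpha/beta-type,EQMKLEIAS,525.1123,2,0.85,1,-3.7,1.2459,26.26,19.75,6.51,INCORRECT
SASP - gamma-type,AQQVR,601.6790,1,1.22,0,-1.95,0.7843,11.89,6.23,5.66,INCORRECT
SASP - gamma-type,EFASE,582.5829,1,0.65,0,-2.58,1.0583,22.38,14.57,7.81,INCORRECT
SASP - gamma-type,QNQQSAGQQGQFGTEFASETDAQQVR,1421.4511,2,1.90,0,-1.72,1.6016,24.73,32.70,-7.97,INCORRECT
SASP - gamma-type,QQSAAGQGQFGTEFASETNAQQVRKQNQ,1014.0562,3,1.64,2,-1.43,1.6228,27.28,33.60,-6.32,INCORRECT
SASP - gamma-type,KQNQQSAAGQGQFGTEFASETNAQQVRK,1014.0705,3,2.36,2,-1.27,1.6228,27.37,33.73,-6.36,INCORRECT
SASP - B. subtilis,ALKDDPLQEAVQKKKNNR,1048.6888,2,0.78,4,-1.49,1.4324,37.98,27.43,10.55,INCORRECT
SASP SspI,PGLGVLFEV,931.1109,1,0.78,0,0.81,1.408,3.28,28.40,-25.12,INCORRECT
SASP Tlp,QNGYR,637.6682,1,0.54,0,-2.24,0.9333,91.35,10.80,80.55,INCORRECT
SASP - gamma-type,KQNQQSAGQQGQFGTEFASETDAQQVR,990.6917,3,6.97,1,-1.43,1.6123,23.22,33.27,-10.05,POTENTIAL_FALSE_POSITIVE
SASP - gamma-type,QQNQSAEQNKQQNS,816.8161,2,2.81,1,-2.74,1.1461,9.12,17.27,-8.15,POTENTIAL_FALSE_POSITIVE
SASP - gamma-type,KQNQQSAAGQGQFGTEFASETNAQQVR,971.3462,3,5.20,1,-1.33,1.6123,25.79,33.34,-7.55,POTENTIAL_FALSE_POSITIVE
SASP - gamma-type,KQNQQSAAGQGQFGTEFASETNAQQVR,1456.5194,2,5.75,1,-1.33,1.6123,25.84,33.34,-7.50,POTENTIAL_FALSE_POSITIVE
SASP - B. subtilis,VVVSVNTDQDQAQAQSQDGED,1117.6176,2,4.73,0,-2.47,1.4038,19.36,25.77,-6.41,POTENTIAL_FALSE_POSITIVE
SASP - beta-type S,ANGSVGGEITKR,595.1525,2,1.82,1,-1.75,1.2151,22.14,20.24,1.90,POTENTIAL_FALSE_NEGATIVE
SASP - B. subtilis,NVIQGALEDAGSALKDDPLQEAVQKK,913.6775,3,2.36,2,-0.88,1.6381,38.31,34.52,3.79,POTENTIAL_FALSE_NEGATIVE
SASP - B. subtilis,LTGGVTPQGDLEGNTHNDPKTELEER,936.9845,3,2.69,1,-1.59,1.5917,27.91,32.48,-4.57,POTENTIAL_FALSE_NEGATIVE
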
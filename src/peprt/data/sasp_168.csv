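protein_label,peptide_sequence,mz,charge,xcorr,missed_cleavages,clogp,log_sum_k1,t_r_exp,t_r_pred,delta_t_r,printed_group
SASP - alpha-type,LVSFAQQNMGGGQF,742.8313,2,4.73,0,-0.78,1.5218,28.61,30.85,-2.24,CORRECT
SASP - beta-type S,ANGSVGGEITK,517.0593,2,2.40,0,-1.58,1.1878,16.22,19.49,-3.27,CORRECT
SASP - alpha/beta-type,LEIASEFGVQLGAETTSR,637.0292,3,0.54,0,-1.08,1.5661,19.25,32.05,-12.80,INCORRECT
SASP - alpha/beta-type,DLGFYDTVK,1058.1664,1,0.79,0,-2.79,1.3818,96.39,24.82,71.57,INCORRECT
SASP - beta-type S,LVSFAQQQMGGR,1322.5195,1,0.65,0,-1.39,1.3947,81.37,26.30,55.07,INCORRECT
SASP - beta-type S,LEIASEFGVNLGADTTSR,941.0171,2,2.07,0,-1.25,1.5661,40.37,31.92,8.45,INCORRECT
SASP - gamma-type,QQNQSAEQNK,588.0960,2,0.84,0,-1.72,1,5.64,13.34,-7.70,INCORRECT
SASP - B. subtilis,DAAVAK,574.6503,1,0.92,0,-2.75,0.8503,9.64,7.74,1.90,POTENTIAL_FALSE_NEGATIVE
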
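dataset,peptide_sequence,field,note
calibration_model_proteins,YICENQDTISSKL,log_sum_k1,printed value 1.4238 is inconsistent with every retention-factor assignment fitting the other rows (reconstruction ~1.435); excluded from the default retention-factor solve
calibration_model_proteins,YICENQDTISSKL,delta_t_r,printed 1.24 breaks the table's ascending sort order; transcribed verbatim
calibration_model_proteins,YICENQDTISSKL,mz,printed 732.67 matches neither unmodified nor carboxymethylated cysteine
calibration_model_proteins,FYLPNCNKNGFYHSR,missed_cleavages,printed 0 but the sequence has an internal K (position 8); any tryptic rule counts 1
calibration_model_proteins,*,mz,cysteine-containing rows from HSA and RibB are printed with carboxymethyl-Cys (+58.04 Da per C) while those from BSA/BML/IGFBP-1 match unmodified cysteine
sasp_dprpe,ANNNSGNSNNLLVPGAAQAIDQMK,printed_group,listed in the correct-by-Xcorr block although Xcorr 3.41 is below the 3.75 threshold for charge 3; strict thresholds reclassify it POTENTIAL_FALSE_NEGATIVE
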
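paper_id,species,phenotype_id,pop_a,pop_b,pst,fst_neutral,fst_nonneutral,n_loci_nonneutral,n_loci_total,mean_n_individuals,method,marker,analysis_group,common_garden
paper000,species000,trait00,P00,P01,0.28877655307593353,0.02675157828475716,0.0803152651200861,604,3235,61.87007379512673,outlier,qtl,non_bayesian,no
paper000,species000,trait00,P00,P02,0.342100663691081,0.04839150693086948,0.08795505769078552,636,3235,61.87007379512673,outlier,qtl,non_bayesian,no
paper001,species001,trait00,P00,P01,0.5785261126899934,0.020174851594176896,0.1001351159514164,464,3258,72.77327635601445,gwas,aflp,gwas_specific,no
paper001,species001,trait00,P00,P02,0.8077203274637834,0.03159074563718666,0.0871911102756069,614,3258,72.77327635601445,gwas,aflp,gwas_specific,no
paper002,species002,trait00,P00,P01,0.4870069211901205,0.3645079485919507,0.5067964005653935,78,1700,51.99881052432097,outlier,qtl,non_bayesian,no
paper002,species002,trait00,P00,P02,0.7663260648515158,0.09685447296541094,0.27424961028117173,50,1700,51.99881052432097,outlier,qtl,non_bayesian,no
paper003,species003,trait00,P00,P01,0.2069747332569348,0.14814596352010315,0.24804223328267885,293,618,41.90487704703008,candidate,msat,non_bayesian,yes
paper003,species003,trait00,P00,P02,0.8557896135311313,0.9179369433924192,0.8628524911890917,268,618,41.90487704703008,candidate,msat,non_bayesian,yes
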
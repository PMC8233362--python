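chemistry,ratio,n_sc,n_bb,n_x,E_kPa,beta,E0_kPa,lambda_max_exp,lambda_max_calc
NCO:OH,1:1,14,889,50,18.6,0.24,27.8,2.1,2.0
NCO:OH,1:2,14,889,100,11.1,0.12,13.5,2.7,2.9
NCO:OH,1:4,14,889,200,4.2,0.10,5.1,3.2,3.2
NCO:OH,1:8,14,889,400,2.1,0.08,2.3,3.6,3.5
NCO:OH,1:1,70,304,50,3.0,0.31,5.3,1.9,1.8
NCO:OH,1:2,70,304,100,1.3,0.26,2.1,2.2,2.0
F:M,1:1,14,889,50,15.3,0.23,22.3,2.1,2.1
F:M,2:1,14,889,100,6.3,0.14,7.8,2.7,2.6
F:M,4:1,14,889,200,1.5,0.12,1.8,2.9,2.8
PCMA,1.5,14,889,100,4.8,0.06,5.2,4.2,4.1
PCMA,3,14,889,200,1.7,0.05,1.8,4.9,4.5
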
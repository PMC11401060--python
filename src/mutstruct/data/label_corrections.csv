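protein,position,wt,mt,label
TREM2,47,R,H,Disease-causing
TREM2,62,R,H,Disease-causing
TREM2,66,T,M,Disease-causing
TREM2,136,R,Q,Disease-causing
TREM2,157,H,Y,Disease-causing
TREM2,223,T,I,Disease-causing
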
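duration_s,speed_m_s,grade_pct
120,1.34,0
120,1.34,2
120,1.34,4
120,1.34,6
120,1.34,8
120,1.34,10
120,1.34,12
120,1.34,14
120,1.34,16
120,1.34,18
120,1.34,20
120,1.34,22
120,1.34,24
120,1.34,26
120,1.34,28
120,1.34,30
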
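time_s,speed_m_s,grade_pct,hr_bpm,rpe
0,0,0,70,6
120,1.34,0,95,8
240,1.34,2,115,10
360,1.34,4,133,12
480,1.34,6,150,14
600,1.34,8,155,16
720,1.34,10,160,18.5
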
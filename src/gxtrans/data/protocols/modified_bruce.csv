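duration_s,speed_m_s,grade_pct
60,0.76,0.0
60,0.76,1.67
60,0.76,3.33
60,0.76,5.0
60,0.76,6.67
60,0.76,8.33
60,0.76,10.0
60,0.879,10.67
60,0.998,11.33
60,1.118,12.0
60,1.252,12.67
60,1.386,13.33
60,1.52,14.0
60,1.639,14.67
60,1.758,15.33
60,1.878,16.0
60,1.997,16.67
60,2.116,17.33
60,2.235,18.0
60,2.31,18.67
60,2.384,19.33
60,2.459,20.0
60,2.533,20.67
60,2.608,21.33
60,2.682,22.0
60,2.682,22.0
60,2.682,22.0
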
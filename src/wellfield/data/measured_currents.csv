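code,voltage_V,frequency_Hz,pulse_ms,I_measured_A
1 V_20 Hz,1,20,3.6,0.012
1 V_7.9 Hz,1,7.9,10,0.012
5 V_20 Hz,5,20,3.6,0.067
5 V_7.9 Hz,5,7.9,10,0.069
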
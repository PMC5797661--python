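animal_id,group,n_sample_areas,n_terminals,density_all,total_asym,density_asym,total_sym,density_sym,terminal_length_mean,terminal_length_sem,synapse_length_mean,synapse_length_sem,total_axon,density_axon
control_1,control,493,4600,6.60,1.22e9,5.94,1.36e8,0.66,469.4,7.2,211.8,2.4,0.70e8,0.34
control_2,control,475,2267,5.29,1.03e9,4.89,0.84e8,0.40,470.4,15.5,205.0,5.65,1.09e8,0.52
control_3,control,487,2632,5.99,1.19e9,5.56,0.93e8,0.43,500.5,15.8,204.1,5.2,1.19e8,0.54
control_4,control,404,2256,6.00,1.16e9,5.47,1.12e8,0.53,514.4,15.9,207.7,4.5,0.99e8,0.48
stress_1,stress,415,2312,6.16,1.05e9,5.65,0.94e8,0.51,450.2,9.0,213.7,3.4,0.82e8,0.47
stress_2,stress,450,2397,5.90,1.06e9,5.54,0.68e8,0.36,486.9,16.3,203.4,5.0,0.69e8,0.35
stress_3,stress,402,1867,5.19,0.92e9,4.73,0.89e8,0.46,480.2,14.9,219.9,6.0,0.64e8,0.32
stress_4,stress,405,2321,6.37,0.92e9,5.84,0.83e8,0.53,511.1,14.0,211.9,4.5,0.59e8,0.36
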
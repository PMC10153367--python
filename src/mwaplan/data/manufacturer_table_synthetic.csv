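# SYNTHETIC manufacturer ablation-size table (not vendor data).
# Generated by scripts/make_synthetic_table.py: bioheat simulations at a fixed
# reference source model, baseline perfusion on, no vessel subdomain.
# Columns: generator power (W), ablation duration (min), ablation length and
# maximum diameter (mm) of the Omega >= 1 damage region.
power_W,time_min,length_mm,diameter_mm
80.0,3.0,41.0,23.7
80.0,4.0,43.0,25.7
80.0,5.0,43.0,27.5
80.0,6.0,45.0,28.4
80.0,7.0,45.0,29.3
80.0,8.0,45.0,30.2
80.0,9.0,47.0,30.9
80.0,10.0,47.0,31.5
90.0,3.0,41.0,24.7
90.0,4.0,43.0,26.5
90.0,5.0,45.0,27.8
90.0,6.0,45.0,29.1
90.0,7.0,45.0,29.8
90.0,8.0,47.0,30.9
90.0,9.0,47.0,31.5
90.0,10.0,47.0,32.0
100.0,3.0,43.0,25.2
100.0,4.0,43.0,27.1
100.0,5.0,45.0,28.6
100.0,6.0,45.0,29.4
100.0,7.0,47.0,30.5
100.0,8.0,47.0,31.5
100.0,9.0,47.0,31.9
100.0,10.0,49.0,32.8
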
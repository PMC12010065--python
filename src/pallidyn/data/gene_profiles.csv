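metric,AOPEP_mean,AOPEP_sd,GNAL_mean,GNAL_sd,KMT2B_mean,KMT2B_sd,PANK2_mean,PANK2_sd,PLA2G6_mean,PLA2G6_sd,SGCE_mean,SGCE_sd,THAP1_mean,THAP1_sd,TOR1A_mean,TOR1A_sd,VPS16_mean,VPS16_sd
firing_rate,15.35,6.9,13.41,9.73,16.71,21.76,20.3,26.36,16.73,10.59,14.95,11.96,23.96,17.74,20.21,15.46,17.15,10.99
firing_regularity,0.23,0.32,-0.13,0.46,-0.02,0.43,0.32,0.49,-0.02,0.49,-0.14,0.36,0.33,0.4,0.06,0.4,0.06,0.47
cv,1.14,0.34,1.82,0.8,1.6,1.1,1.18,0.64,1.59,0.77,1.77,1.07,1.45,1.12,1.49,0.85,1.51,0.98
local_variation,0.72,0.15,0.79,0.24,0.81,0.25,0.69,0.23,0.75,0.22,0.82,0.23,0.62,0.16,0.78,0.22,0.77,0.19
isi_mean_ms,78.08,31.98,116.25,77.52,117.18,91.53,91.23,68.5,89.38,66.0,96.52,58.25,62.93,44.84,82.49,64.41,78.93,46.01
isi_std_ms,73.12,37.73,134.28,107.47,128.45,111.73,84.74,72.9,95.99,82.11,108.96,74.33,56.4,46.15,87.91,85.91,83.2,63.71
isi_skewness,1.8,0.3,2.19,0.49,2.07,0.44,1.75,0.38,2.07,0.42,2.18,0.39,1.73,0.35,1.98,0.38,1.99,0.43
isi_corr_coefficient,0.13,0.14,0.02,0.1,0.04,0.15,0.12,0.2,0.04,0.12,0.05,0.11,0.12,0.17,0.05,0.12,0.06,0.13
asymmetry_index,0.36,0.19,0.17,0.2,0.15,0.16,0.33,0.32,0.21,0.21,0.17,0.21,0.34,0.26,0.22,0.27,0.23,0.28
burst_index,20.63,15.63,31.6,26.26,24.96,26.92,25.09,34.62,18.29,25.71,24.05,25.68,8.34,5.93,28.82,28.41,22.42,19.42
burst_duration_s,0.11,0.1,0.2,0.18,0.17,0.25,0.29,0.29,0.12,0.12,0.13,0.18,0.17,0.24,0.21,0.35,0.13,0.17
burst_frequency_hz,208.1,103.23,116.8,60.91,130.3,83.52,100.28,88.02,141.29,71.41,142.58,76.78,144.22,95.62,137.48,80.32,151.7,80.46
interburst_duration_s,3.01,0.49,3.89,2.07,4.58,3.61,3.11,1.4,3.05,1.62,3.52,1.84,2.14,0.73,3.28,1.67,3.12,1.7
burst_count,1.33,0.58,4.48,4.55,3.85,3.79,3.0,1.78,5.28,4.52,4.55,3.89,4.18,2.09,4.0,6.98,3.19,2.49
burst_avg_spike_count,12.17,10.75,10.28,5.61,10.13,13.89,11.08,10.17,9.23,6.6,9.09,7.45,10.33,4.48,11.08,7.73,9.71,7.29
burst_spike_proportion_pct,5.41,4.35,3.55,3.69,3.0,3.72,5.81,6.37,3.25,3.38,2.57,2.8,2.94,1.78,3.73,3.4,4.03,4.09
pause_index,0.95,0.59,2.04,6.08,1.39,1.73,1.38,1.5,1.58,5.03,1.18,3.65,1.03,2.21,0.99,1.94,1.03,2.8
pause_ratio,0.14,0.11,0.5,1.5,0.37,0.73,0.28,0.45,0.36,1.26,0.27,0.91,0.17,0.4,0.19,0.3,0.19,0.61
pause_duration_s,0.52,0.43,1.05,0.99,0.81,0.96,0.55,0.68,0.67,1.04,0.75,0.82,0.45,0.38,0.62,0.75,0.65,0.98
pause_frequency_hz,3.42,1.77,2.41,1.74,3.4,4.43,3.87,3.3,3.22,2.18,2.87,2.23,4.9,3.92,4.22,3.42,3.61,2.39
pause_count,5.02,2.94,7.92,6.29,12.9,15.55,5.6,5.63,10.88,8.76,9.82,7.13,5.51,3.84,8.39,6.85,7.37,4.62
pause_spike_proportion_pct,7.29,2.79,9.48,4.29,9.2,3.89,6.8,3.34,9.5,3.77,10.03,4.2,6.02,3.29,8.19,3.42,8.62,4.03
pause_time_proportion_pct,35.28,15.78,55.27,23.15,47.5,22.61,32.64,18.63,52.39,24.8,52.63,23.3,31.49,20.6,41.62,20.5,43.79,22.75
delta_freq_hz,0.92,0.0,1.25,0.71,1.01,0.11,0.93,0.05,1.04,0.28,1.04,0.32,0.92,0.0,1.0,0.35,0.96,0.25
theta_freq_hz,3.66,0.0,4.87,1.44,4.21,1.02,3.83,0.55,4.46,1.16,4.42,1.19,3.8,0.51,4.12,0.9,4.19,0.95
alpha_freq_hz,8.79,1.66,8.33,1.1,8.76,1.34,8.51,1.61,9.11,1.38,8.86,1.26,8.63,1.52,8.66,1.33,8.67,1.33
beta_freq_hz,14.65,5.07,16.48,4.48,16.74,5.56,20.4,5.02,17.51,4.82,18.82,5.02,15.14,3.79,17.23,5.84,17.8,5.37
gamma_freq_hz,52.25,10.99,41.12,14.3,41.46,17.0,46.09,17.64,36.48,7.04,41.73,15.38,34.76,6.81,41.46,15.89,39.73,13.71
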
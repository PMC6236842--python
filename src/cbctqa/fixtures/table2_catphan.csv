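name,wcbdi_cGy,noise_hu,noise_sd,lcd_mm,cnr,cnr_sd,mtf_f50_lpcm,mtf_f50_sd,mtf_f10_lpcm,mtf_f10_sd,uniformity_hu,uniformity_sd,hu_constancy_hu,hu_constancy_sd
Image Gently,0.09,62.4,0.8,>=15,0.20,0.3,4.4,0.5,7.0,0.3,8.3,3.3,18.8,9.1
80kV_Half_15mA,0.14,50.2,0.3,>=15,0.27,0.2,3.9,0.2,6.7,0.1,7.5,0.5,8.3,4.0
80kV_Half_60mA,0.52,25.1,0.3,9 ~ 15,0.58,0.5,4.2,0.2,7.2,0.2,5.7,2.3,11.0,3.5
80kV_Half_126mA,1.09,17.9,0.3,6,0.91,0.1,4.1,0.1,7.0,0.2,5.1,1.1,9.3,0.6
80kV_Full_15mA,0.28,36.5,0.2,8 ~ 9,0.39,0.3,4.2,0.1,7.2,0.1,3.7,2.0,9.0,4.6
80kV_Full_30mA,0.53,25.0,0.2,7,0.49,0.1,4.1,0.2,7.0,0.2,2.0,0.2,22.7,1.2
80kV_Full_45mA,0.79,20.7,0.3,6,0.66,0.2,4.1,0.1,7.1,0.1,3.3,1.4,13.7,2.5
80kV_Full_60mA,1.04,18.0,0.2,5 ~ 6,0.74,0.2,4.1,0.1,7.0,0.1,2.5,0.9,14.0,3.0
80kV_Full_70mA,1.22,16.6,0.0,5,0.80,0.2,4.1,0.1,7.1,0.1,3.7,0.9,14.0,1.0
Head,0.32,34.5,0.3,>=15,0.43,0.4,4.0,0.2,7.0,0.1,7.5,1.3,10.6,3.7
Half_15mA_Slow,0.63,24.9,0.3,>=15,0.56,0.3,4.1,0.1,7.0,0.1,7.4,2.2,11.9,1.0
Half_15mA_VerySlow,0.95,20.7,0.1,>=15,0.91,0.3,4.1,0.1,7.1,0.1,6.2,0.5,12.0,3.7
Half_15mA_Slowest,1.27,18.5,0.2,>=9,0.79,0.3,4.1,0.0,7.0,0.0,6.3,1.8,12.5,1.8
Half_30mA,0.63,25.5,0.2,9,0.66,0.2,4.0,0.3,6.9,0.3,6.3,3.0,13.0,3.6
Half_30mA_Slow,1.27,18.3,0.2,7 ~ 8,0.90,0.4,4.1,0.1,7.1,0.1,3.9,0.9,9.8,3.1
Half_45mA,0.95,21.0,0.2,8,0.78,0.3,4.0,0.1,7.0,0.1,3.8,0.5,13.0,1.4
Half_60mA,1.27,18.7,0.2,7,0.93,0.1,4.1,0.0,7.1,0.1,3.4,1.5,13.0,4.1
Full_15mA,0.62,24.6,0.3,7,0.58,0.2,4.2,0.2,7.1,0.2,2.5,1.5,5.0,2.6
Full_15mA_Slow,1.09,17.6,0.1,5,0.87,0.1,4.0,0.1,7.0,0.1,2.8,0.4,2.5,0.0
Full_30mA,1.18,17.9,0.1,5,0.86,0.2,4.2,0.0,7.2,0.0,1.6,0.8,6.0,2.6
125kV_Half_15mA,0.63,26.5,0.3,9 ~ 15,0.55,0.1,4.1,0.0,7.1,0.0,5.9,2.0,20.5,2.6
125kV_Full_15mA,1.23,18.7,0.3,5,0.75,0.2,4.1,0.1,7.0,0.1,4.1,0.1,8.8,2.8
125kV_Full_30mA,2.29,13.6,0.2,4 ~ 5,1.09,0.3,4.1,0.1,7.0,0.1,3.9,1.2,10.7,3.1
140kV_Half_15mA,0.87,23.9,0.2,9 ~ 15,0.53,0.1,4.0,0.1,7.0,0.1,8.5,2.8,17.0,4.4
140kV_Full_15mA,1.70,16.7,0.2,5,0.69,0.3,4.2,0.0,7.1,0.0,4.9,0.7,8.8,2.8
140kV_Full_30mA,3.11,12.3,0.1,5,0.90,0.2,4.1,0.0,7.1,0.1,5.7,1.5,9.4,0.9
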
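protocol,mAs,dose_cGy,roi_mean_hu,roi_noise_hu,bkg_mean_hu,bkg_noise_hu,cnr
Sim CT,142,5.94,6.5,6.7,28.3,7.5,3.24
Head,150,0.32,-61.8,37.3,-26.4,35.4,0.95
Full_15mA,270,0.62,-28.5,28.1,4.2,27.6,1.16
Full_30mA,540,1.18,6.2,18.1,25.7,19.2,1.08
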
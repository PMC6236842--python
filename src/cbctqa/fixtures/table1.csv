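name,kvp,current_mA,pulse_width_ms,trajectory,gantry_speed_deg_s,mAs,projections
Image Gently,80,10,20,Half,6.0,100,500
80kV_Half_15mA,80,15,20,Half,6.0,150,500
80kV_Half_60mA,80,60,20,Half,6.0,600,500
80kV_Half_126mA,80,126,20,Half,6.0,1260,500
80kV_Full_15mA,80,15,20,Full,6.0,270,900
80kV_Full_30mA,80,30,20,Full,6.0,540,900
80kV_Full_45mA,80,45,20,Full,6.0,810,900
80kV_Full_60mA,80,60,20,Full,6.0,1080,900
80kV_Full_70mA,80,70,20,Full,6.0,1260,900
Head,100,15,20,Half,6.0,150,500
Half_15mA_Slow,100,15,20,Half,3.0,300,1000
Half_15mA_VerySlow,100,15,20,Half,2.0,450,1500
Half_15mA_Slowest,100,15,20,Half,1.5,600,2000
Half_30mA,100,30,20,Half,6.0,300,500
Half_30mA_Slow,100,30,20,Half,3.0,600,1000
Half_45mA,100,45,20,Half,6.0,450,500
Half_60mA,100,60,20,Half,6.0,600,500
Full_15mA,100,15,20,Full,6.0,270,900
Full_15mA_Slow,100,15,20,Full,3.0,540,1800
Full_30mA,100,30,20,Full,6.0,540,900
125kV_Half_15mA,125,15,20,Half,6.0,150,500
125kV_Full_15mA,125,15,20,Full,6.0,270,900
125kV_Full_30mA,125,30,20,Full,6.0,540,900
140kV_Half_15mA,140,15,20,Half,6.0,150,500
140kV_Full_15mA,140,15,20,Full,6.0,270,900
140kV_Full_30mA,140,30,20,Full,6.0,540,900
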
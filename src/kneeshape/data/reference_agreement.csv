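measure,bias,bias_ci_lo,bias_ci_hi,loa_lo,loa_lo_ci_lo,loa_lo_ci_hi,loa_hi,loa_hi_ci_lo,loa_hi_ci_hi,r2,ccc,units
B-score,0.100,0.052,0.140,-0.896,-0.979,-0.813,1.096,1.013,1.179,0.938,0.967,
z-score,-0.424,-0.475,-0.374,-1.471,-1.558,-1.384,0.622,0.535,0.709,0.910,0.924,
MF.tAB,-54.983,-61.218,-48.748,-184.522,-195.322,-173.722,74.556,63.756,85.356,0.964,0.969,mm^2
LF.tAB,-42.792,-47.019,-38.569,-130.563,-137.880,-123.245,44.975,37.657,52.292,0.970,0.971,mm^2
MT.tAB,-5.858,-9.235,-2.482,-75.997,-81.840,-70.149,64.380,58.432,70.128,0.962,0.978,mm^2
LT.tAB,-21.329,-23.896,-18.762,-74.659,-79.106,-70.213,32.001,27.555,36.447,0.965,0.968,mm^2
TrFMed.tAB,-28.346,-30.714,-25.978,-77.544,-81.646,-73.443,20.853,16.751,24.955,0.932,0.918,mm^2
TrFLat.tAB,-39.387,-43.002,-35.773,-114.477,-120.738,-108.217,35.703,29.442,41.963,0.947,0.945,mm^2
Medial 3DJSW,1.044,0.979,1.110,-0.315,-0.428,-0.202,2.404,2.290,2.517,0.575,0.635,mm
Lateral 3DJSW,0.424,0.342,0.507,-1.295,-1.438,-1.151,2.144,2.000,2.287,0.467,0.489,mm
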
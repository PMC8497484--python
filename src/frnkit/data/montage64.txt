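# 61-channel 10-20/10-10 scalp montage + mastoids (M1, M2) + right suborbital (SO2)
# name x y z   (unit-sphere head coordinates, +x right, +y anterior, +z superior)
Fp1 -0.329991 +0.940726 -0.078359
Fpz +0.001272 +0.999811 -0.019408
Fp2 +0.330899 +0.940402 -0.078426
AF7 -0.620076 +0.775350 -0.119742
AF3 -0.389395 +0.887815 +0.245268
AFz +0.002623 +0.915822 +0.401576
AF4 +0.404395 +0.880143 +0.248623
AF8 +0.620326 +0.775159 -0.119684
F7 -0.847627 +0.512395 -0.137767
F5 -0.784679 +0.584687 +0.205963
F3 -0.595220 +0.629189 +0.499834
F1 -0.314606 +0.651404 +0.690432
Fz +0.003526 +0.660786 +0.750566
F2 +0.335604 +0.654987 +0.677025
F4 +0.606623 +0.635512 +0.477633
F6 +0.791456 +0.580704 +0.190737
F8 +0.846108 +0.514567 -0.139004
FT7 -0.976104 +0.170633 -0.134558
FC5 -0.929019 +0.224309 +0.294293
FC3 -0.708119 +0.267286 +0.653548
FC1 -0.375357 +0.286639 +0.881445
FCz +0.004053 +0.295142 +0.955445
FC2 +0.386023 +0.293400 +0.874587
FC4 +0.717488 +0.273238 +0.640743
FC6 +0.929583 +0.233006 +0.285628
FT8 +0.973730 +0.183483 -0.134845
T7 -0.976571 -0.185874 -0.108447
C5 -0.927952 -0.159047 +0.337058
C3 -0.706876 -0.125802 +0.696060
C1 -0.371708 -0.102635 +0.922659
Cz +0.003983 -0.091066 +0.995837
C2 +0.390044 -0.099645 +0.915389
C4 +0.720988 -0.117092 +0.682983
C6 +0.934162 -0.143011 +0.326939
T8 +0.978884 -0.172815 -0.109187
TP7 -0.876639 -0.475591 -0.072917
CP5 -0.818335 -0.478616 +0.318205
CP3 -0.618606 -0.457546 +0.638732
CP1 -0.326425 -0.434692 +0.839339
CPz +0.003504 -0.429705 +0.902963
CP2 +0.351645 -0.431251 +0.830884
CP4 +0.637648 -0.446439 +0.627771
CP6 +0.831488 -0.460056 +0.311412
TP8 +0.880320 -0.468673 -0.073370
P7 -0.701950 -0.711819 -0.024101
P5 -0.637048 -0.722449 +0.268769
P3 -0.480960 -0.714878 +0.507570
P1 -0.251075 -0.706414 +0.661771
Pz +0.002804 -0.700597 +0.713552
P2 +0.275926 -0.695760 +0.663161
P4 +0.498504 -0.703519 +0.506513
P6 +0.642647 -0.718535 +0.265919
P8 +0.706832 -0.706954 -0.024575
PO7 -0.489979 -0.871377 +0.024946
PO3 -0.321642 -0.888450 +0.327418
POz +0.001891 -0.896107 +0.443835
PO4 +0.324496 -0.889716 +0.321103
PO8 +0.495193 -0.868443 +0.024285
O1 -0.252329 -0.964666 +0.075827
Oz +0.000929 -0.991960 +0.126546
O2 +0.256398 -0.963610 +0.075607
M1 -0.726044 -0.379484 -0.573456
M2 +0.724712 -0.380199 -0.574666
SO2 +0.236891 +0.673234 -0.700456
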
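batch,sex,age,r0,r1,r2,r3,r4
a,F,36.455,-0.840156,-0.824481,0.650593,0.743254,0.543154
a,M,28.868,-0.16551,0.232161,0.316686,-0.081311,0.971429
a,F,24.545,0.223596,0.678914,0.067579,0.289119,0.631288
a,M,31.092,-0.957156,-0.319671,-0.270373,-0.938878,-0.175142
a,M,21.276,1.994941,-0.865831,1.168278,-1.98287,-0.234885
a,M,36.553,0.662753,0.586222,0.911227,0.493347,-0.248725
a,M,32.633,0.037648,0.857976,0.008696,-1.575686,-1.033287
a,M,35.162,-0.419452,0.497161,0.342426,0.390485,-0.327253
b,F,27.091,0.95854,0.22559,-0.109347,1.456775,-1.261926
b,F,39.414,0.436946,-0.781738,-0.99584,1.486972,-1.069402
b,M,37.862,1.312494,0.080747,0.846531,1.365385,-0.598485
b,F,35.568,0.376702,-0.479718,-1.487334,-0.447112,-1.9227
b,F,23.893,-0.197247,-0.000226,-0.705479,0.621837,0.699228
b,F,29.334,0.443736,0.337516,-0.733618,0.794562,-1.550022
b,M,20.876,0.960967,0.440308,-1.32732,1.134424,-0.262264
c,M,23.086,-0.83181,-2.524481,-0.199018,-1.54129,-0.074254
c,F,33.661,-0.469407,1.742491,-0.835098,-1.932896,-0.249014
c,F,34.895,-0.192004,1.402863,0.669155,-0.000381,1.548624
c,F,39.35,-2.164268,-1.395653,-1.797206,-1.045734,-2.42736
c,F,26.517,0.389211,-0.811112,-2.559128,-1.921811,-0.06108
c,M,27.409,1.173378,2.295423,3.779407,-0.219827,-1.785353
c,M,29.391,-2.984864,-0.125205,-1.438117,-1.3815,-1.256936
c,M,23.789,-0.197107,0.992372,-0.080131,-1.022089,-1.849916
c,F,22.598,-2.844556,-1.180831,-0.575296,1.975102,-0.317615
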
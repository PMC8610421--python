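group,variable,n,mean,sd,pi_lower,pi_upper,min,max
human_male,L2,48,4.4,3.3,-2.1,10.9,-3.4,12.8
human_female,L2,31,2.1,2.1,-2.0,6.2,-2.1,6.0
Pan,L2,43,4.6,3.0,-1.3,10.5,-1.1,12.4
Gorilla,L2,31,2.3,2.7,-3.0,7.6,-4.0,8.3
Pongo,L2,10,5.3,4.7,-3.9,14.5,-0.4,14.4
human_male,L3,48,2.4,3.1,-3.7,8.5,-4.8,11.2
human_female,L3,31,1.3,2.6,-3.8,6.4,-3.4,6.6
Pan,L3,43,4.5,3.1,-1.6,10.6,-2.4,10.9
Gorilla,L3,31,2.6,2.0,-1.3,6.5,-2.2,7.5
Pongo,L3,10,6.1,2.0,2.2,10.0,3.2,8.6
human_male,L4,48,-0.5,2.8,-6.0,5.0,-8.3,4.8
human_female,L4,31,-1.5,2.9,-7.2,4.2,-7.9,4.6
Pan,L4,43,3.5,3.4,-3.2,10.2,-3.6,10.9
Gorilla,L4,31,1.3,2.5,-3.6,6.2,-3.9,7.1
Pongo,L4,10,4.8,3.8,-2.6,12.2,-1.0,11.3
human_male,L5,48,-5.9,2.9,-11.6,-0.2,-11.6,1.8
human_female,L5,31,-6.5,3.1,-12.6,-0.4,-12.3,2.2
Pan,L5,43,-0.5,2.8,-6.0,5.0,-5.9,7.0
Gorilla,L5,31,-0.8,2.2,-5.1,3.5,-6.2,3.5
Pongo,L5,10,2.0,4.1,-6.0,10.0,-5.2,8.0
human_male,combined,48,0.4,7.8,-15.0,15.7,-15.6,15.5
human_female,combined,31,-4.9,8.1,-20.8,11.0,-18.2,11.2
Pan,combined,43,12.1,8.8,-5.1,29.3,-5.2,31.7
Gorilla,combined,31,5.4,5.7,-5.8,16.6,-8.1,15.7
Pongo,combined,10,18.1,9.5,8.6,27.6,0.04,36.0
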
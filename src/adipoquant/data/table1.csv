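Patient,BW at baseline [kg],BW after 2 weeks [kg],BW after 12 weeks [kg],BMI at baseline [kg/m2],BMI after 2 weeks [kg/m2],BMI after 3 months [kg/m2],VAT change from baseline (%),SCAT change from baseline (%),LTW change from baseline (%),Therapy,Response
1,90.9,85.0,79.9,26.0,24.3,22.8,-44.83,-34.87,-1.31,PD-1-mAb,PD
2,96.2,100.3,100.8,32.5,33.9,34.1,4.86,0.26,1.11,CTLA-4-mAb,PD
3,85.7,85.9,89.3,31.5,31.6,32.8,0.32,4.04,8.59,PD-1-mAb,MIXED
4,57.2,57.5,54.7,22.3,22.5,21.4,-5.76,-3.78,1.65,PD-1-mAb,PD
5,82.6,82.0,80.6,27.9,27.7,27.2,-14.50,-7.48,1.76,PD-1-mAb,MIXED
6,84.5,85.0,86.7,26.1,26.2,26.8,-4.07,-2.48,-5.72,CTLA-4-mAb,RTT
7,67.4,66.0,66.4,24.8,24.2,24.4,1.96,-0.49,-4.13,PD-1-mAb,RTT
8,85.1,84.0,79.0,27.5,27.1,25.5,-38.13,-17.07,6.76,PD-1-mAb,MIXED
9,100.3,99.0,96.2,32.8,32.3,31.4,-6.44,-4.58,-0.31,PD-1-mAb,MIXED
10,93.1,92.1,92.9,28.1,27.8,28.0,1.88,-0.72,1.42,PD-1-mAb,RTT
11,71.3,72.0,70.0,25.0,25.2,24.5,12.96,-0.06,2.31,BRAF,PD
12,61.2,60.0,62.3,22.5,22.0,22.9,-3.50,2.69,4.80,PD-1-mAb,PD
13,65.7,68.3,67.3,21.2,22.0,21.7,16.67,13.85,1.54,PD-1-mAb,PD
14,85.3,86.2,86.5,24.4,24.7,24.7,1.96,1.25,3.04,PD-1-mAb,RTT
15,87.6,82.0,75.5,28.6,26.8,24.7,-13.86,-19.49,-14.67,BRAF,MIXED
16,112.5,110.0,113.0,32.5,31.8,32.7,-1.16,-8.36,4.00,PD-1-mAb,PD
17,82.2,83.0,83.3,25.4,25.6,25.7,7.17,4.89,-3.62,PD-1-mAb,RTT
18,53.6,55.7,55.1,20.0,20.7,20.5,17.13,7.42,6.15,PD-1-mAb,MIXED
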
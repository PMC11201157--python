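id,name,r,g,b
0,Black Background,0,0,0
1,Abdominal Wall,210,125,130
2,Liver,120,30,30
3,Gastrointestinal Tract,230,170,170
4,Fat,230,210,100
5,Grasper,170,170,180
6,Connective Tissue,200,180,160
7,Blood,180,20,40
8,Cystic Duct,120,200,140
9,L-hook Electrocautery,100,120,180
10,Gallbladder,110,160,70
11,Hepatic Vein,60,60,140
12,Liver Ligament,220,150,90
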
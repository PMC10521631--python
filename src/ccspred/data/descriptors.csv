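amino_acid,scale_name,value
A,volume,88.6
R,volume,173.4
N,volume,114.1
D,volume,111.1
C,volume,108.5
Q,volume,143.8
E,volume,138.4
G,volume,60.1
H,volume,153.2
I,volume,166.7
L,volume,166.7
K,volume,168.6
M,volume,162.9
F,volume,189.9
P,volume,112.7
S,volume,89.0
T,volume,116.1
W,volume,227.8
Y,volume,193.6
V,volume,140.0
A,polarity,8.1
R,polarity,10.5
N,polarity,11.6
D,polarity,13.0
C,polarity,5.5
Q,polarity,10.5
E,polarity,12.3
G,polarity,9.0
H,polarity,10.4
I,polarity,5.2
L,polarity,4.9
K,polarity,11.3
M,polarity,5.7
F,polarity,5.2
P,polarity,8.0
S,polarity,9.2
T,polarity,8.6
W,polarity,5.4
Y,polarity,6.2
V,polarity,5.9
A,hydropathy,1.8
R,hydropathy,-4.5
N,hydropathy,-3.5
D,hydropathy,-3.5
C,hydropathy,2.5
Q,hydropathy,-3.5
E,hydropathy,-3.5
G,hydropathy,-0.4
H,hydropathy,-3.2
I,hydropathy,4.5
L,hydropathy,3.8
K,hydropathy,-3.9
M,hydropathy,1.9
F,hydropathy,2.8
P,hydropathy,-1.6
S,hydropathy,-0.8
T,hydropathy,-0.7
W,hydropathy,-0.9
Y,hydropathy,-1.3
V,hydropathy,4.2
A,hydrophilicity,-0.5
R,hydrophilicity,3.0
N,hydrophilicity,0.2
D,hydrophilicity,3.0
C,hydrophilicity,-1.0
Q,hydrophilicity,0.2
E,hydrophilicity,3.0
G,hydrophilicity,0.0
H,hydrophilicity,-0.5
I,hydrophilicity,-1.8
L,hydrophilicity,-1.8
K,hydrophilicity,3.0
M,hydrophilicity,-1.3
F,hydrophilicity,-2.5
P,hydrophilicity,0.0
S,hydrophilicity,0.3
T,hydrophilicity,-0.4
W,hydrophilicity,-3.4
Y,hydrophilicity,-2.3
V,hydrophilicity,-1.5
A,solvent_exposed_area,15.0
R,solvent_exposed_area,67.0
N,solvent_exposed_area,49.0
D,solvent_exposed_area,50.0
C,solvent_exposed_area,5.0
Q,solvent_exposed_area,56.0
E,solvent_exposed_area,55.0
G,solvent_exposed_area,10.0
H,solvent_exposed_area,34.0
I,solvent_exposed_area,13.0
L,solvent_exposed_area,16.0
K,solvent_exposed_area,85.0
M,solvent_exposed_area,20.0
F,solvent_exposed_area,10.0
P,solvent_exposed_area,45.0
S,solvent_exposed_area,32.0
T,solvent_exposed_area,32.0
W,solvent_exposed_area,17.0
Y,solvent_exposed_area,41.0
V,solvent_exposed_area,14.0
A,accessible_surface_area,115.0
R,accessible_surface_area,225.0
N,accessible_surface_area,160.0
D,accessible_surface_area,150.0
C,accessible_surface_area,135.0
Q,accessible_surface_area,180.0
E,accessible_surface_area,190.0
G,accessible_surface_area,75.0
H,accessible_surface_area,195.0
I,accessible_surface_area,175.0
L,accessible_surface_area,170.0
K,accessible_surface_area,200.0
M,accessible_surface_area,185.0
F,accessible_surface_area,210.0
P,accessible_surface_area,145.0
S,accessible_surface_area,115.0
T,accessible_surface_area,140.0
W,accessible_surface_area,255.0
Y,accessible_surface_area,230.0
V,accessible_surface_area,155.0
A,accessible_surface_area_folded,31.5
R,accessible_surface_area_folded,93.8
N,accessible_surface_area_folded,62.2
D,accessible_surface_area_folded,60.9
C,accessible_surface_area_folded,13.9
Q,accessible_surface_area_folded,74.0
E,accessible_surface_area_folded,72.3
G,accessible_surface_area_folded,25.2
H,accessible_surface_area_folded,46.7
I,accessible_surface_area_folded,23.0
L,accessible_surface_area_folded,29.0
K,accessible_surface_area_folded,110.3
M,accessible_surface_area_folded,30.5
F,accessible_surface_area_folded,28.7
P,accessible_surface_area_folded,53.7
S,accessible_surface_area_folded,44.2
T,accessible_surface_area_folded,46.0
W,accessible_surface_area_folded,41.7
Y,accessible_surface_area_folded,59.1
V,accessible_surface_area_folded,23.5
A,local_flexibility,0.357
R,local_flexibility,0.529
N,local_flexibility,0.463
D,local_flexibility,0.511
C,local_flexibility,0.346
Q,local_flexibility,0.493
E,local_flexibility,0.497
G,local_flexibility,0.544
H,local_flexibility,0.323
I,local_flexibility,0.462
L,local_flexibility,0.365
K,local_flexibility,0.466
M,local_flexibility,0.295
F,local_flexibility,0.314
P,local_flexibility,0.509
S,local_flexibility,0.507
T,local_flexibility,0.444
W,local_flexibility,0.305
Y,local_flexibility,0.420
V,local_flexibility,0.386
A,pk_side_chain,0.0
R,pk_side_chain,12.48
N,pk_side_chain,0.0
D,pk_side_chain,3.65
C,pk_side_chain,8.18
Q,pk_side_chain,0.0
E,pk_side_chain,4.25
G,pk_side_chain,0.0
H,pk_side_chain,6.0
I,pk_side_chain,0.0
L,pk_side_chain,0.0
K,pk_side_chain,10.53
M,pk_side_chain,0.0
F,pk_side_chain,0.0
P,pk_side_chain,0.0
S,pk_side_chain,0.0
T,pk_side_chain,0.0
W,pk_side_chain,0.0
Y,pk_side_chain,10.07
V,pk_side_chain,0.0
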
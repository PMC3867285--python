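load toy.pdb, cube_struct
hide everything
bg_color white
show cartoon, cube_struct
color grey80, cube_struct
select cube_ligands, cube_struct and hetatm and not resn HOH
show sticks, cube_ligands
set_color cube_col01, [1.000,0.000,0.000]
set_color cube_col02, [1.000,0.224,0.224]
set_color cube_col03, [1.000,0.443,0.443]
set_color cube_col04, [1.000,0.667,0.667]
set_color cube_col05, [1.000,0.890,0.890]
set_color cube_col06, [0.890,0.890,1.000]
set_color cube_col07, [0.667,0.667,1.000]
set_color cube_col08, [0.443,0.443,1.000]
set_color cube_col09, [0.224,0.224,1.000]
set_color cube_col10, [0.000,0.000,1.000]
# score set 'entropy' -> selections cube_bin01..10
select cube_bin01, cube_struct and chain A and resi 5+15+25
color cube_col01, cube_bin01
select cube_bin02, cube_struct and chain A and resi 3+8+18
color cube_col02, cube_bin02
select cube_bin03, cube_struct and chain A and resi 4+12+19
color cube_col03, cube_bin03
select cube_bin04, cube_struct and chain A and resi 7+13
color cube_col04, cube_bin04
select cube_bin05, cube_struct and chain A and resi 2+11+24+27
color cube_col05, cube_bin05
select cube_bin06, cube_struct and chain A and resi 1+29
color cube_col06, cube_bin06
select cube_bin07, cube_struct and chain A and resi 9+14+17+23
color cube_col07, cube_bin07
select cube_bin08, cube_struct and chain A and resi 6+16+20
color cube_col08, cube_bin08
select cube_bin09, cube_struct and chain A and resi 22+30
color cube_col09, cube_bin09
select cube_bin10, cube_struct and chain A and resi 10+21+26+28
color cube_col10, cube_bin10
show surface, cube_struct and chain A
show cartoon, cube_struct and chain A
scene entropy, store
# score set 'determinant' -> selections cube2_bin01..10
select cube2_bin01, cube_struct and chain A and resi 4+15+27
color cube_col01, cube2_bin01
select cube2_bin02, cube_struct and chain A and resi 21+25+26
color cube_col02, cube2_bin02
select cube2_bin04, cube_struct and chain A and resi 1+6+7+10+16+17+19+20+22+24+30
color cube_col04, cube2_bin04
select cube2_bin07, cube_struct and chain A and resi 2+9+11+12+13
color cube_col07, cube2_bin07
select cube2_bin08, cube_struct and chain A and resi 3+8
color cube_col08, cube2_bin08
select cube2_bin09, cube_struct and chain A and resi 14+18+28
color cube_col09, cube2_bin09
select cube2_bin10, cube_struct and chain A and resi 5+23+29
color cube_col10, cube2_bin10
show surface, cube_struct and chain A
show cartoon, cube_struct and chain A
scene determinant, store
# hide a poorly scoring tier with e.g.: hide surface, cube_bin10
deselect
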
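state,plan,point,reference_dose,reference_sd,clinical1_dose,clinical1_diff,clinical2_dose,clinical2_diff,new_dose,new_diff
inflated,open,1,94.8,1.4,86.7,-8.5,96.5,1.8,94.2,-0.6
inflated,open,2,93.6,1.8,88.8,-5.2,97.1,3.7,95.9,2.4
inflated,open,3,91.9,1.1,91.4,-0.5,91.4,-0.5,91.4,-0.5
inflated,open,4,92.8,2.7,93.4,0.6,93.4,0.6,93.4,0.6
inflated,vmat,1,99.9,2.4,97.7,-2.2,98.6,-1.3,98.8,-1.1
inflated,vmat,2,95.3,0.9,94.0,-1.3,96.0,0.8,95.6,0.3
inflated,vmat,3,91.0,0.9,90.3,-0.8,90.7,-0.4,90.6,-0.5
inflated,vmat,4,93.7,1.8,90.9,-3.0,91.2,-2.7,91.3,-2.6
inflated,4fld-imrt,1,106.9,0.1,100.2,-6.3,102.8,-3.9,104.0,-2.7
inflated,4fld-imrt,2,104.1,1.0,96.0,-7.8,98.0,-5.8,99.3,-4.6
inflated,4fld-imrt,3,97.2,0.4,99.5,2.4,99.5,2.4,99.5,2.4
inflated,4fld-imrt,4,93.8,1.9,98.5,5.0,98.5,5.0,98.5,5.0
deflated,open,1,95.7,1.8,85.3,-10.8,103.5,8.2,93.8,-2.0
deflated,open,2,99.1,1.7,89.1,-10.0,104.7,5.7,97.6,-1.5
deflated,open,3,97.3,2.1,96.1,-1.2,103.5,6.4,96.4,-0.9
deflated,open,4,96.6,0.8,97.7,1.1,105.3,9.0,98.0,1.4
deflated,vmat,1,103.8,2.1,98.2,-5.4,109.9,5.9,100.4,-3.3
deflated,vmat,2,103.0,2.3,97.8,-5.1,108.7,5.5,99.2,-3.7
deflated,vmat,3,96.8,0.6,92.6,-4.3,102.4,5.8,95.0,-1.8
deflated,vmat,4,100.7,1.2,94.4,-6.2,105.7,5.0,97.8,-2.9
deflated,4fld-imrt,1,98.2,3.5,89.3,-9.0,104.0,5.9,95.7,-2.5
deflated,4fld-imrt,2,99.0,1.7,88.8,-10.3,102.1,3.1,95.6,-3.4
deflated,4fld-imrt,3,104.0,1.1,100.4,-3.4,107.7,3.6,99.9,-3.9
deflated,4fld-imrt,4,100.6,2.2,101.2,0.6,108.2,7.6,100.8,0.2
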
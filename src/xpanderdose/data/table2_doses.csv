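plan,point,reference_dose,clinical1_dose,clinical1_diff,clinical2_dose,clinical2_diff,new_dose,new_diff
conventional,CW1,4562.6,4564.9,0.05,4563.2,0.01,4563.5,0.02
conventional,CW2,4561.8,4566.5,0.10,4563.0,0.03,4563.1,0.03
conventional,skin1,5336.7,4815.8,-9.76,5161.4,-3.28,4985.8,-6.58
conventional,skin2,5213.7,4813.0,-7.69,5046.6,-3.21,4928.3,-5.47
vmat,CW1,4972.2,4968.3,-0.08,4967.0,-0.10,4951.5,-0.42
vmat,CW2,4887.8,4872.0,-0.32,4875.8,-0.25,4857.4,-0.62
vmat,skin1,5090.2,5050.3,-0.78,5070.0,-0.40,5050.9,-0.77
vmat,skin2,5250.2,4892.8,-6.81,5099.1,-2.88,4988.6,-4.98
4fld-imrt,CW1,4972.4,4971.3,-0.02,4973.2,0.02,4973.7,0.03
4fld-imrt,CW2,5021.9,5020.8,-0.02,5024.0,0.04,5024.8,0.06
4fld-imrt,skin1,5312.0,4986.7,-6.12,5183.5,-2.42,5119.4,-3.63
4fld-imrt,skin2,5533.9,5205.9,-5.93,5378.7,-2.80,5333.0,-3.63
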
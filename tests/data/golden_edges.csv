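predictor,outcome,stability,mean_coef,selection_count
x005_L1,use,1.0,-0.664429144255138,10
x001_L1,use,1.0,0.6054312008120573,10
x003_L2,use,1.0,-0.23703360240308777,10
x002_L2,use,1.0,0.21377763313753623,10
x006_L2,use,1.0,0.00022958668834473505,10
x005_L2,use,0.9,0.2367801040491076,9
x004_L1,use,0.8,-0.22212608195977887,8
x002_L1,use,0.8,0.13084309277753445,8
x006_L1,use,0.7,0.13789883688719964,7
x001_L2,use,0.7,0.03313830821867318,7
x004_L2,use,0.7,0.03133656395473809,7
x003_L1,use,0.5,-0.1510423096809914,5
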
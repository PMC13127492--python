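predictor,outcome,theta,se,ci_low,ci_high,n_rows,n_subjects,n_folds_used,stability
x005_L1,use,-0.1757064973979391,0.03569054867735856,-0.2456586873940355,-0.10575430740184265,253,104,3,1.0
x001_L1,use,0.14133308362386085,0.040244371820142906,0.062455564275942094,0.2202106029717796,253,104,3,1.0
x003_L2,use,-0.007793023781995458,0.03370084115492137,-0.07384545869434658,0.05825941113035566,253,104,3,1.0
x002_L2,use,0.02629100798350489,0.03238097925381904,-0.0371745451381191,0.08975656110512889,253,104,3,1.0
x006_L2,use,0.007197334063294182,0.030683442030048823,-0.05294110723732407,0.06733577536391244,253,104,3,1.0
x005_L2,use,0.05285178672963126,0.04232019882803929,-0.030094278791899957,0.13579785225116248,253,104,3,0.9
x004_L1,use,-0.010720863175587847,0.028829187367130086,-0.06722503211871991,0.045783305767544226,253,104,3,0.8
x002_L1,use,0.04495340497433442,0.03744836907295027,-0.02844404968841173,0.11835085963708057,253,104,3,0.8
x006_L1,use,0.04265118797713321,0.024518612114369905,-0.00540440871793927,0.09070678467220569,253,104,3,0.7
x001_L2,use,0.002759894838273567,0.03422461047870241,-0.0643191090848953,0.06983889876144242,253,104,3,0.7
x004_L2,use,-0.009373854672834513,0.03053340536419139,-0.06921822951201173,0.0504705201663427,253,104,3,0.7
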
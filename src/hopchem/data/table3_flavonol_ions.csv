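compound_id,rt_min,lambda_max_nm,mode,mz,rel_abundance,assignment
quercetin-3-O-rutinoside,3.83,354,positive,611.4,100,M+H
quercetin-3-O-rutinoside,3.83,354,positive,303.1,1,aglycone+H
quercetin-3-O-rutinoside,3.83,354,negative,609.3,100,M-H
quercetin-3-O-rutinoside,3.83,354,negative,1219.3,30,2M-H
quercetin-3-O-glucoside,3.96,354,positive,465.3,100,M+H
quercetin-3-O-glucoside,3.96,354,positive,303.0,8,aglycone+H
quercetin-3-O-glucoside,3.96,354,negative,463.3,100,M-H
quercetin-3-O-glucoside,3.96,354,negative,927.3,60,2M-H
kaempferol-3-O-rutinoside,4.18,347,positive,595.3,100,M+H
kaempferol-3-O-rutinoside,4.18,347,positive,287.7,2,aglycone+H
kaempferol-3-O-rutinoside,4.18,347,negative,593.3,100,M-H
kaempferol-3-O-rutinoside,4.18,347,negative,1187.6,20,2M-H
quercetin-3-O-(6''-O-malonyl)-glucoside,4.20,354,positive,551.3,100,M+H
quercetin-3-O-(6''-O-malonyl)-glucoside,4.20,354,negative,505.3,90,M-CO2-H
quercetin-3-O-(6''-O-malonyl)-glucoside,4.20,354,negative,549.2,25,M-H
quercetin-3-O-(6''-O-malonyl)-glucoside,4.20,354,negative,1099.6,100,2M-H
kaempferol-3-O-glucoside,4.30,348,positive,449.3,100,M+H
kaempferol-3-O-glucoside,4.30,348,positive,287.4,8,aglycone+H
kaempferol-3-O-glucoside,4.30,348,negative,447.4,100,M-H
kaempferol-3-O-glucoside,4.30,348,negative,895.4,35,2M-H
kaempferol-3-O-(6''-O-malonyl)-glucoside,4.60,348,positive,535.2,100,M+H
kaempferol-3-O-(6''-O-malonyl)-glucoside,4.60,348,negative,489.3,100,M-CO2-H
kaempferol-3-O-(6''-O-malonyl)-glucoside,4.60,348,negative,533.2,35,M-H
kaempferol-3-O-(6''-O-malonyl)-glucoside,4.60,348,negative,1067.4,95,2M-H
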
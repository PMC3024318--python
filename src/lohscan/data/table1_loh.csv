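snp_id,band,tn_ratio,p_value,gene,in_microdeletion
rs2085575,6p25.3-24.3,1.2073538,0.004,F13A1,false
rs3024317,6p25.3-24.3,1.1449631,0.0181,F13A1,false
rs4960294,6p25,1.1457735,0.0298,RREB1,false
rs6597256,6p25,1.1318706,0.017,RREB1,false
rs267184,6p24-23,1.1431448,0.0253,BMP6,false
rs504083,6p24.2,1.1581754,0.0281,GCNT2,true
rs1318748,6p24.2,1.1529571,0.0371,GCNT2,true
rs11759513,6p25-24,1.1893557,0.0232,NEDD9,true
rs2137873,6p23,1.1861716,0.011,ATXN1,false
rs235147,6p23,1.1638418,0.03,ATXN1,false
rs236949,6p23,1.1905564,0.0047,ATXN1,false
rs2143083,6p22.3-22.2,1.3092179,0.0001,ALDH5A1,false
rs2267633,6p21.31,1.1809524,0.0033,GABBR1,true
rs2076483,6p21.31,1.2159952,0.0007,GABBR1,true
rs29230,6p21.31,1.1642882,0.0007,GABBR1,true
rs2517713,6p21.3,1.1925186,0.0109,HCP5P3,false
rs9260734,6p21.3,1.2099734,0.0033,HCG2P6,true
rs3869062,6p21.3,1.1733857,0.0101,HCG2P6,true
rs5009448,6p21.3,1.1841842,0.0164,MICD,true
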
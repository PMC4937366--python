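specimen_id,element,coll_percent,d13C,d15N,pC,pN,cn_printed,c14_age,c14_err
IGVR 203334,Mandible,1.3,-21.8,7.1,8.2,2.4,4.1,5580,26
IGVR 63017-15,Left Parietal fragment,2.9,-20.7,9.3,34.7,12.1,3.4,5675,23
IGVR 63017-2,Occipital,4.5,-20.7,9.3,38.2,13.3,3.3,5530,23
IGVR 63017-4,Left Temporal fragment,1.4,-20.4,5.7,30.2,10.0,3.5,25530,107
IGVR 63017-12,Cranial fragment,0.8,-21.2,6.6,17.8,5.6,3.7,10190,33
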
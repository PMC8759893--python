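category,pathology_type,n_cases
malignant,Invasive ductal carcinoma,2
malignant,Ductal carcinoma in situ,4
malignant,Papillary carcinoma,10
malignant,Mucinous carcinoma,20
malignant,Invasive lobular carcinoma,10
malignant,Invasive adenocarcinoma,18
benign,Fibroadenoma,3
benign,Adenopathy,4
benign,Papilloma,11
benign,Benign phyllodes tumor,24
benign,Adenopathy with papilloma,10
benign,Interstitial sclerosis,18
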
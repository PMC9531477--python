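(Gallus_gallus:0.25,(Nipponia_nippon:0.10,(Anhinga_anhinga:0.09,(Scopus_umbretta:0.08,((Egretta_garzetta:0.04,Nycticorax_nycticorax:0.04):0.02,Cochlearius_cochlearius:0.06):0.03):0.02):0.02):0.05);
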
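(L_tulipifera:92.92,(M_henryi:44.02,((((((M_lacandonica:3.3150000000000004,M_macrocarpa:3.3150000000000004):3.3150000000000004,(M_mexicana:3.3150000000000004,M_ofeliae:3.3150000000000004):3.3150000000000004):3.3149999999999995,((M_zoquepopolucae:3.3150000000000004,M_wetteri:3.3150000000000004):3.3150000000000004,(M_allenii:3.3150000000000004,M_dodecapetala:3.3150000000000004):3.3150000000000004):3.3149999999999995):3.3149999999999995,(((M_kichuana:3.3150000000000004,M_pastazaensis:3.3150000000000004):3.3150000000000004,(M_zamorana:3.3150000000000004,M_rimachii:3.3150000000000004):3.3150000000000004):3.3149999999999995,((M_silvioi:3.3150000000000004,M_virolinensis:3.3150000000000004):3.3150000000000004,(M_wolfii:3.3150000000000004,M_ovata:3.3150000000000004):3.3150000000000004):3.3149999999999995):3.3149999999999995):22.71,((M_emarginata:10.9,M_splendens:10.9):3.1799999999999997,(M_bankardiorum:10.33,(M_coronata:6.886666666666667,(M_jaenensis:3.4433333333333334,M_ptaritepuiana:3.4433333333333334):3.4433333333333334):3.4433333333333334):3.75):21.89):2.9399999999999977,(((M_iltisiana:13.83,(M_panamensis:6.915,M_sharpii:6.915):6.915):9.15,(M_grandiflora:6.0,(M_macrophylla:4.5,(M_dealbata:3.0,(M_rzedowskiana:1.5,M_vovidesii:1.5):1.5):1.5):1.5):16.98):7.280000000000001,(M_septentrionalis:14.69,(M_obovata:13.692,(M_grandis:12.693999999999999,(M_kachirachirai:11.696,(M_foveolata:10.698,(M_acuminata:9.7,M_biondii:9.7):0.9980000000000011):0.9979999999999993):0.9979999999999993):0.9980000000000011):0.9979999999999993):15.570000000000002):8.649999999999995):5.1100000000000065):48.9);
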
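# Tip geography for the 39-taxon Magnoliaceae fixture.
#
# Each taxon is assigned a locality (country / state, following the
# sampled species' native occurrence rather than garden collection
# sites), and the gazetteer maps localities to operational areas.  The
# published analysis shows its area coding only graphically, so this
# coding is a best-effort, editable transcription: adjust the gazetteer
# or a taxon's locality to recode.  All ranges have at most two areas.
gazetteer:
  China: Asia
  Japan: Asia
  "Florida, USA": Nearctic
  "Southeastern USA": Nearctic
  "Eastern USA": Nearctic
  "Veracruz, Mexico": Mexican-Transition-Zone
  "San Luis Potosi, Mexico": Mexican-Transition-Zone
  "Jalisco, Mexico": Mexican-Transition-Zone
  "Morelos, Mexico": Mexican-Transition-Zone
  "Chiapas, Mexico": Mesoamerica
  "Oaxaca, Mexico": Mesoamerica
  "Chiriqui, Panama": Mesoamerica
  "Cocle, Panama": Mesoamerica
  "Puntarenas, Costa Rica": Mesoamerica
  Haiti: Caribbean
  "Puerto Rico": Caribbean
  "Lesser Antilles": Caribbean
  "Antioquia, Colombia": Andes-North
  "Cajamarca, Peru": Andes-North
  "Pereira, Colombia": Andes-North
  "Virolin, Colombia": Andes-North
  "Bolivar, Venezuela": Brazil-Boreal
  "Loreto, Peru": Brazil-Boreal
  "Napo, Ecuador": Pacific
  "Pastaza, Ecuador": Pacific
  "Zamora, Ecuador": Pacific
  Brazil: Brazil-Atlantic
taxa:
  M_henryi: China
  M_kachirachirai: China
  M_septentrionalis: China
  M_dealbata: "Veracruz, Mexico"
  M_grandiflora: "Florida, USA"
  M_macrophylla: "Southeastern USA"
  M_rzedowskiana: "San Luis Potosi, Mexico"
  M_vovidesii: "Jalisco, Mexico"
  M_iltisiana: "Jalisco, Mexico"
  M_panamensis: "Chiriqui, Panama"
  M_sharpii: "Chiapas, Mexico"
  M_grandis: China
  M_foveolata: China
  M_obovata: Japan
  M_emarginata: Haiti
  M_splendens: "Puerto Rico"
  M_bankardiorum: "Zamora, Ecuador"
  M_coronata: "Antioquia, Colombia"
  M_jaenensis: "Cajamarca, Peru"
  M_ptaritepuiana: "Bolivar, Venezuela"
  M_allenii: "Cocle, Panama"
  M_dodecapetala: "Lesser Antilles"
  M_kichuana: "Napo, Ecuador"
  M_lacandonica: "Chiapas, Mexico"
  M_macrocarpa: "Oaxaca, Mexico"
  M_mexicana: "Morelos, Mexico"
  M_ofeliae: "Jalisco, Mexico"
  M_ovata: Brazil
  M_pastazaensis: "Pastaza, Ecuador"
  M_rimachii: "Loreto, Peru"
  M_silvioi: "Antioquia, Colombia"
  M_virolinensis: "Virolin, Colombia"
  M_wetteri: "Puntarenas, Costa Rica"
  M_wolfii: "Pereira, Colombia"
  M_zamorana: "Zamora, Ecuador"
  M_zoquepopolucae: "Veracruz, Mexico"
  M_acuminata: "Eastern USA"
  M_biondii: China
  L_tulipifera: "Eastern USA"
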
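{
  "comment": "Nitrogen-assimilation routes, N-cycle module markers, amino-acid biosynthesis steps and transporter fallbacks for oligotrophic surface-ocean communities. Enzyme ids are gene symbols; the ko_alias column is an editable convenience mapping and is not used by the logic.",
  "vocabulary": {
    "urease": "K01428",
    "nitrilase": "K01501",
    "gdhA": "K00262",
    "amt": "K03320",
    "nrtA": "K15576",
    "nirA": "K00366",
    "cynS": "K01725",
    "nmo": "K00459",
    "fmdA": "K01455",
    "narG": "K00370",
    "napA": "K02567",
    "narB": "K00367",
    "nasA": "K00372",
    "narsB": null,
    "nirK": "K00368",
    "nirS": "K15864",
    "norB": "K04561",
    "nosZ": "K00376",
    "amoA": "K10944",
    "hao": "K10535",
    "nifH": "K02588",
    "hzsA": "K20932",
    "hdh": "K20935",
    "metC": "K01760",
    "metH": "K00548",
    "serC": "K00831",
    "serB": "K01079",
    "glyA": "K00600",
    "ltaE": "K01620",
    "asdA": "K00133",
    "ALT": "K00814",
    "tyrB": "K00832",
    "tyrC": "K00220",
    "pheA2": "K04518",
    "ilvE": "K00826",
    "leuB": "K00052",
    "ilvA": "K01754",
    "trpB": "K01696",
    "proC": "K00286",
    "thrC": "K01733",
    "cysK": "K01738",
    "asnB": "K01953",
    "glnA": "K01915",
    "aspC": "K00813",
    "gltB": "K00265",
    "lysA": "K01586",
    "argH": "K01755",
    "hisB": "K01693"
  },
  "transporter_vocabulary": {
    "betT": "K02168",
    "betS": null,
    "agcS": "K03310"
  },
  "routes": {
    "urea_to_ammonia": [["urease"]],
    "nitrile_to_ammonia": [["nitrilase"]],
    "glutamate_deamination": [["gdhA"]],
    "ammonium_uptake": [["amt"]],
    "nitrite_assimilation": [["nrtA", "nmo"], ["nirA"]],
    "cyanate_to_ammonia": [["cynS"]]
  },
  "modules": {
    "dissimilatory_nitrate_reduction": ["narG", "napA"],
    "assimilatory_nitrate_reduction": ["narB", "nasA", "narsB", "nirA"],
    "denitrification": ["nirK", "nirS", "norB", "nosZ"],
    "nitrification": ["amoA", "hao"],
    "nitrogen_fixation": ["nifH"],
    "anammox": ["hzsA", "hdh"]
  },
  "aa_pathways": {
    "Met": [["metC"], ["metH"]],
    "Ser": [["serC"], ["serB"]],
    "Gly": [["ltaE", "serC"], ["ltaE", "serB"], ["ltaE", "glyA"]],
    "Ala": [["asdA", "ALT"]],
    "Tyr": [["tyrC"], ["tyrB"]],
    "Phe": [["pheA2"], ["tyrB"]],
    "Val": [["ilvE"]],
    "Leu": [["leuB"]],
    "Ile": [["ilvA"]],
    "Trp": [["trpB"]],
    "Pro": [["proC"]],
    "Thr": [["thrC"]],
    "Cys": [["cysK"]],
    "Asn": [["asnB"]],
    "Gln": [["glnA"]],
    "Asp": [["aspC"]],
    "Glu": [["gltB"]],
    "Lys": [["lysA"]],
    "Arg": [["argH"]],
    "His": [["hisB"]]
  },
  "conversions": [
    ["Ser", "Gly", "glyA"],
    ["Thr", "Gly", "ltaE"]
  ],
  "transporters": {
    "Gly": ["betT", "betS", "agcS"],
    "Ala": ["agcS"]
  },
  "observed_sets": {
    "prochlorococcus_nitrogen": ["urease", "nitrilase", "gdhA", "amt", "nrtA", "nirA", "cynS", "nmo", "fmdA"],
    "community_nitrogen": ["urease", "nitrilase", "gdhA", "amt", "nrtA", "nirA", "cynS", "nmo", "fmdA", "narG", "narB", "nasA", "nirK", "norB", "amoA", "hao"],
    "table1_absent_enzymes": ["metC", "serB", "ltaE", "asdA", "ALT", "tyrB"],
    "table1_transporters": ["betT", "betS", "agcS"]
  }
}
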
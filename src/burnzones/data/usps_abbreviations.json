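{
  "version": "2024.1",
  "source": "USPS Publication 28, Appendix C1 (subset of terms seen in incident names)",
  "abbreviations": {
    "AVENUE": "AVE",
    "BOULEVARD": "BLVD",
    "BRANCH": "BR",
    "BRIDGE": "BRG",
    "CANYON": "CYN",
    "CENTER": "CTR",
    "CREEK": "CRK",
    "CROSSING": "XING",
    "DRIVE": "DR",
    "EAST": "E",
    "ESTATE": "EST",
    "FALLS": "FLS",
    "FIELD": "FLD",
    "FLAT": "FLT",
    "FOREST": "FRST",
    "GLEN": "GLN",
    "GROVE": "GRV",
    "HEIGHTS": "HTS",
    "HIGHWAY": "HWY",
    "HOLLOW": "HOLW",
    "ISLAND": "IS",
    "JUNCTION": "JCT",
    "LAKE": "LK",
    "LAKES": "LKS",
    "LANDING": "LNDG",
    "MEADOW": "MDW",
    "MEADOWS": "MDWS",
    "MILL": "ML",
    "MISSION": "MSN",
    "MOUNT": "MT",
    "MOUNTAIN": "MTN",
    "MOUNTAINS": "MTNS",
    "NORTH": "N",
    "ORCHARD": "ORCH",
    "PARKWAY": "PKWY",
    "PINES": "PNES",
    "POINT": "PT",
    "PRAIRIE": "PR",
    "RANCH": "RNCH",
    "RAPIDS": "RPDS",
    "RIDGE": "RDG",
    "RIVER": "RIV",
    "ROAD": "RD",
    "SOUTH": "S",
    "SPRING": "SPG",
    "SPRINGS": "SPGS",
    "SQUARE": "SQ",
    "STATION": "STA",
    "STREET": "ST",
    "SUMMIT": "SMT",
    "TRAIL": "TRL",
    "TUNNEL": "TUNL",
    "TURNPIKE": "TPKE",
    "VALLEY": "VLY",
    "VIEW": "VW",
    "VILLAGE": "VLG",
    "VISTA": "VIS",
    "WELLS": "WLS",
    "WEST": "W"
  }
}
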
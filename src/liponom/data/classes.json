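{
  "comment": "Lipid class templates. backbone: Hill formula of the headgroup/backbone with free OH/NH at every chain slot. slots: linkage in {ester, amide, thioester, ether, none}; linkages other than 'none' consume one backbone H on attachment. hca: FA (fatty acyl), ether (alkyl or alkenyl), LCB (long-chain base), ST (sterol). imlf_alias: moiety family used to name multi-chain (iMLF) fragments.",
  "classes": [
    {
      "symbol": "PC",
      "category": "glycerophospholipid",
      "backbone": "C8H20NO6P",
      "slots": [{"linkage": "ester", "hca": "FA"}, {"linkage": "ester", "hca": "FA"}],
      "adducts": {"+": ["+H", "+Na"], "-": ["+CH3COO", "+HCOO"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "LPC",
      "category": "glycerophospholipid",
      "backbone": "C8H20NO6P",
      "slots": [{"linkage": "ester", "hca": "FA"}],
      "adducts": {"+": ["+H", "+Na"], "-": ["+CH3COO", "+HCOO"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "PC O-",
      "category": "glycerophospholipid",
      "backbone": "C8H20NO6P",
      "slots": [{"linkage": "ether", "hca": "ether"}, {"linkage": "ester", "hca": "FA"}],
      "adducts": {"+": ["+H", "+Na"], "-": ["+CH3COO", "+HCOO"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "PE",
      "category": "glycerophospholipid",
      "backbone": "C5H14NO6P",
      "slots": [{"linkage": "ester", "hca": "FA"}, {"linkage": "ester", "hca": "FA"}],
      "adducts": {"+": ["+H", "+Na"], "-": ["-H"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "PE O-",
      "category": "glycerophospholipid",
      "backbone": "C5H14NO6P",
      "slots": [{"linkage": "ether", "hca": "ether"}, {"linkage": "ester", "hca": "FA"}],
      "adducts": {"+": ["+H", "+Na"], "-": ["-H"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "PS",
      "category": "glycerophospholipid",
      "backbone": "C6H14NO8P",
      "slots": [{"linkage": "ester", "hca": "FA"}, {"linkage": "ester", "hca": "FA"}],
      "adducts": {"+": ["+H"], "-": ["-H"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "PI",
      "category": "glycerophospholipid",
      "backbone": "C9H19O11P",
      "slots": [{"linkage": "ester", "hca": "FA"}, {"linkage": "ester", "hca": "FA"}],
      "adducts": {"+": ["+H"], "-": ["-H"]},
      "imlf_alias": "glycerol",
      "head_label_site": "inositol"
    },
    {
      "symbol": "PA",
      "category": "glycerophospholipid",
      "backbone": "C3H9O6P",
      "slots": [{"linkage": "ester", "hca": "FA"}, {"linkage": "ester", "hca": "FA"}],
      "adducts": {"+": ["+NH4"], "-": ["-H"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "CL",
      "category": "glycerophospholipid",
      "backbone": "C9H22O13P2",
      "slots": [
        {"linkage": "ester", "hca": "FA"},
        {"linkage": "ester", "hca": "FA"},
        {"linkage": "ester", "hca": "FA"},
        {"linkage": "ester", "hca": "FA"}
      ],
      "adducts": {"-": ["-H", "-2H"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "DAG",
      "category": "glycerolipid",
      "backbone": "C3H8O3",
      "slots": [{"linkage": "ester", "hca": "FA"}, {"linkage": "ester", "hca": "FA"}],
      "adducts": {"+": ["+NH4", "+Na"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "TAG",
      "category": "glycerolipid",
      "backbone": "C3H8O3",
      "slots": [
        {"linkage": "ester", "hca": "FA"},
        {"linkage": "ester", "hca": "FA"},
        {"linkage": "ester", "hca": "FA"}
      ],
      "adducts": {"+": ["+NH4", "+Na"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "SM",
      "category": "sphingolipid",
      "backbone": "C5H12NO3P",
      "slots": [{"linkage": "none", "hca": "LCB"}, {"linkage": "amide", "hca": "FA"}],
      "adducts": {"+": ["+H", "+Na"], "-": ["+CH3COO", "+HCOO"]},
      "imlf_alias": "Cer"
    },
    {
      "symbol": "Cer",
      "category": "sphingolipid",
      "backbone": "",
      "slots": [{"linkage": "none", "hca": "LCB"}, {"linkage": "amide", "hca": "FA"}],
      "adducts": {"+": ["+H"], "-": ["-H", "+HCOO", "+CH3COO"]},
      "imlf_alias": "Cer"
    },
    {
      "symbol": "SE",
      "category": "sterol",
      "backbone": "",
      "slots": [{"linkage": "none", "hca": "ST"}, {"linkage": "ester", "hca": "FA"}],
      "adducts": {"+": ["+NH4", "+Na"]},
      "imlf_alias": "glycerol",
      "sn_only": true
    },
    {
      "symbol": "ACar",
      "category": "fatty acyl",
      "backbone": "C7H15NO3",
      "slots": [{"linkage": "ester", "hca": "FA"}],
      "adducts": {"+": ["+H"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "ACoA",
      "category": "fatty acyl",
      "backbone": "C21H36N7O16P3S",
      "slots": [{"linkage": "thioester", "hca": "FA"}],
      "adducts": {"-": ["-H", "-2H"]},
      "imlf_alias": "glycerol"
    },
    {
      "symbol": "FA",
      "category": "fatty acyl",
      "backbone": "HO",
      "slots": [{"linkage": "none", "hca": "FA"}],
      "adducts": {"-": ["-H"]},
      "imlf_alias": "glycerol"
    }
  ]
}
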
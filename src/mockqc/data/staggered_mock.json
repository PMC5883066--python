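{
 "community_id": "staggered_mock",
 "kind": "staggered",
 "members": [
  {
   "clone_id": "SAR11",
   "taxon_label": "SAR11",
   "expected_proportion": 0.2
  },
  {
   "clone_id": "Prochlorococcus",
   "taxon_label": "Prochlorococcus",
   "expected_proportion": 0.13
  },
  {
   "clone_id": "SAR86",
   "taxon_label": "SAR86",
   "expected_proportion": 0.09
  },
  {
   "clone_id": "Synechococcus",
   "taxon_label": "Synechococcus",
   "expected_proportion": 0.07
  },
  {
   "clone_id": "Roseobacter",
   "taxon_label": "Roseobacter",
   "expected_proportion": 0.06
  },
  {
   "clone_id": "Flavobacteria",
   "taxon_label": "Flavobacteria",
   "expected_proportion": 0.055
  },
  {
   "clone_id": "SAR116",
   "taxon_label": "SAR116",
   "expected_proportion": 0.05
  },
  {
   "clone_id": "MarineGroupA",
   "taxon_label": "MarineGroupA",
   "expected_proportion": 0.045
  },
  {
   "clone_id": "Thaumarchaea",
   "taxon_label": "Thaumarchaea",
   "expected_proportion": 0.04
  },
  {
   "clone_id": "SAR202",
   "taxon_label": "SAR202",
   "expected_proportion": 0.035
  },
  {
   "clone_id": "OCS155_b",
   "taxon_label": "OCS155_b",
   "expected_proportion": 0.03
  },
  {
   "clone_id": "Planctomyces",
   "taxon_label": "Planctomyces",
   "expected_proportion": 0.03
  },
  {
   "clone_id": "SAR92",
   "taxon_label": "SAR92",
   "expected_proportion": 0.025
  },
  {
   "clone_id": "OM43",
   "taxon_label": "OM43",
   "expected_proportion": 0.022
  },
  {
   "clone_id": "MGII",
   "taxon_label": "MGII",
   "expected_proportion": 0.018
  },
  {
   "clone_id": "SAR324",
   "taxon_label": "SAR324",
   "expected_proportion": 0.018
  },
  {
   "clone_id": "SUP05",
   "taxon_label": "SUP05",
   "expected_proportion": 0.015
  },
  {
   "clone_id": "OM60",
   "taxon_label": "OM60",
   "expected_proportion": 0.012
  },
  {
   "clone_id": "NS5",
   "taxon_label": "NS5",
   "expected_proportion": 0.01
  },
  {
   "clone_id": "NS4",
   "taxon_label": "NS4",
   "expected_proportion": 0.009
  },
  {
   "clone_id": "Actinomarina",
   "taxon_label": "Actinomarina",
   "expected_proportion": 0.008
  },
  {
   "clone_id": "Puniceispirillum",
   "taxon_label": "Puniceispirillum",
   "expected_proportion": 0.007
  },
  {
   "clone_id": "Verrucomicrobia",
   "taxon_label": "Verrucomicrobia",
   "expected_proportion": 0.006
  },
  {
   "clone_id": "Lentisphaerae",
   "taxon_label": "Lentisphaerae",
   "expected_proportion": 0.005
  },
  {
   "clone_id": "OM182",
   "taxon_label": "OM182",
   "expected_proportion": 0.004
  },
  {
   "clone_id": "AEGEAN169",
   "taxon_label": "AEGEAN169",
   "expected_proportion": 0.003
  },
  {
   "clone_id": "Nitrospina",
   "taxon_label": "Nitrospina",
   "expected_proportion": 0.003
  }
 ]
}
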
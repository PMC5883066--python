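{
 "community_id": "even_mock",
 "kind": "even",
 "members": [
  {
   "clone_id": "MGII",
   "taxon_label": "MGII",
   "expected_proportion": 0.09090909090909091
  },
  {
   "clone_id": "SAR11",
   "taxon_label": "SAR11",
   "expected_proportion": 0.09090909090909091
  },
  {
   "clone_id": "Thaumarchaea",
   "taxon_label": "Thaumarchaea",
   "expected_proportion": 0.09090909090909091
  },
  {
   "clone_id": "Prochlorococcus",
   "taxon_label": "Prochlorococcus",
   "expected_proportion": 0.09090909090909091
  },
  {
   "clone_id": "Flavobacteria",
   "taxon_label": "Flavobacteria",
   "expected_proportion": 0.09090909090909091
  },
  {
   "clone_id": "SAR202",
   "taxon_label": "SAR202",
   "expected_proportion": 0.09090909090909091
  },
  {
   "clone_id": "Planctomyces",
   "taxon_label": "Planctomyces",
   "expected_proportion": 0.09090909090909091
  },
  {
   "clone_id": "MarineGroupA",
   "taxon_label": "MarineGroupA",
   "expected_proportion": 0.09090909090909091
  },
  {
   "clone_id": "SAR116",
   "taxon_label": "SAR116",
   "expected_proportion": 0.09090909090909091
  },
  {
   "clone_id": "SAR86",
   "taxon_label": "SAR86",
   "expected_proportion": 0.09090909090909091
  },
  {
   "clone_id": "Synechococcus",
   "taxon_label": "Synechococcus",
   "expected_proportion": 0.09090909090909091
  }
 ]
}
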
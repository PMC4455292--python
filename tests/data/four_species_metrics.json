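{
  "_comment": "Hand-computed structural properties of the four-node toy community (resource + two herbivores + one predator eating both) under the 75%-of-average cutoff.",
  "S": 4,
  "L": 4,
  "links_per_species": 1.0,
  "connectance": 0.25,
  "frac_top": 0.3333333333333333,
  "frac_herbivore": 0.6666666666666666,
  "frac_omnivore": 0.0,
  "frac_cannibal": 0.0,
  "frac_in_loops": 0.0,
  "mean_generality": 1.0,
  "sd_generality": 0.7071067811865476,
  "mean_vulnerability": 1.0,
  "sd_vulnerability": 0.7071067811865476,
  "mean_linkedness": 2.0,
  "sd_linkedness": 0.0,
  "mean_swtl": 2.0,
  "max_swtl": 3.0,
  "mean_flow_tl": 2.0,
  "n_chains": 2,
  "clustering": 0.0,
  "char_path_length": 1.3333333333333333,
  "max_similarity": 0.6666666666666666
}
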
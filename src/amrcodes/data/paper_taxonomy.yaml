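# Bundled reference taxonomy for human-disease animal-model classification codes.
# Equivalent to paper_taxonomy.tsv; one mapping per node. `provenance: inferred`
# marks codes deduced from printed example codes rather than an explicit listing.
nodes:
  - {dimension: A, layer: major, parent_path: "", label: cardiovascular disease, code: "01"}
  - {dimension: A, layer: major, parent_path: "", label: digestive system disease, code: "02"}
  - {dimension: A, layer: major, parent_path: "", label: respiratory system disease, code: "03"}
  - {dimension: A, layer: major, parent_path: "", label: urinary system disease, code: "04"}
  - {dimension: A, layer: major, parent_path: "", label: reproductive system disease, code: "05"}
  - {dimension: A, layer: major, parent_path: "", label: endocrine disease, code: "06"}
  - {dimension: A, layer: major, parent_path: "", label: ophthalmology and otolaryngology disease, code: "07"}
  - {dimension: A, layer: major, parent_path: "", label: oral disease, code: "08"}
  - {dimension: A, layer: major, parent_path: "", label: bone disease, code: "09"}
  - {dimension: A, layer: major, parent_path: "", label: skin disease, code: "10"}
  - {dimension: A, layer: major, parent_path: "", label: nervous system disease, code: "11"}
  - {dimension: A, layer: major, parent_path: "", label: blood system disease, code: "12"}
  - {dimension: A, layer: major, parent_path: "", label: infectious disease, code: "13"}
  - {dimension: A, layer: major, parent_path: "", label: tumor, code: "14"}
  - {dimension: A, layer: major, parent_path: "", label: TCM viscera dialectics disease, code: "15"}
  - {dimension: A, layer: major, parent_path: "", label: other diseases, code: "16"}
  - {dimension: A, layer: intermediate, parent_path: cardiovascular disease, label: myocarditis, code: "01"}
  - {dimension: A, layer: intermediate, parent_path: cardiovascular disease, label: pericarditis, code: "02"}
  - {dimension: A, layer: intermediate, parent_path: cardiovascular disease, label: myocardial infarction, code: "03"}
  - {dimension: A, layer: intermediate, parent_path: cardiovascular disease, label: arrhythmia, code: "04"}
  - {dimension: A, layer: intermediate, parent_path: cardiovascular disease, label: myocardial ischemia, code: "05"}
  - {dimension: A, layer: intermediate, parent_path: cardiovascular disease, label: arterial thrombosis, code: "06"}
  - {dimension: A, layer: intermediate, parent_path: cardiovascular disease, label: hypertension, code: "07"}
  - {dimension: A, layer: intermediate, parent_path: cardiovascular disease, label: atherosclerosis, code: "08"}
  - {dimension: A, layer: intermediate, parent_path: respiratory system disease, label: SARS-CoV-2 infection, code: "12", provenance: inferred}
  - {dimension: B, layer: major, parent_path: "", label: laboratory animal, code: "11"}
  - {dimension: B, layer: intermediate, parent_path: laboratory animal, label: mouse, code: "11"}
  - {dimension: B, layer: intermediate, parent_path: laboratory animal, label: rat, code: "13"}
  - {dimension: B, layer: intermediate, parent_path: laboratory animal, label: guinea pig, code: "15"}
  - {dimension: B, layer: intermediate, parent_path: laboratory animal, label: rabbit, code: "27", provenance: inferred}
  - {dimension: B, layer: minor, parent_path: laboratory animal/mouse, label: BALB/c, code: "001"}
  - {dimension: B, layer: minor, parent_path: laboratory animal/mouse, label: KM, code: "002"}
  - {dimension: B, layer: minor, parent_path: laboratory animal/mouse, label: C57, code: "003"}
  - {dimension: B, layer: minor, parent_path: laboratory animal/mouse, label: ICR-Tg(hACE2), code: "017", provenance: inferred}
  - {dimension: B, layer: minor, parent_path: laboratory animal/rat, label: SD, code: "001"}
  - {dimension: B, layer: minor, parent_path: laboratory animal/rat, label: Wistar, code: "002"}
  - {dimension: B, layer: minor, parent_path: laboratory animal/rabbit, label: New Zealand, code: "001"}
  - {dimension: C, layer: category, parent_path: "", label: spontaneous, code: "01"}
  - {dimension: C, layer: category, parent_path: "", label: induced, code: "02"}
  - {dimension: C, layer: category, parent_path: "", label: genetic engineering, code: "03"}
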
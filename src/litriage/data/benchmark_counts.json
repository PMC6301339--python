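{
  "description": "Published dual-curator evaluation counts for a curation-support pipeline over two annotation axes (GO biological process, disease). All derived percentages are recomputed from these raw counts at run time.",
  "triage_agreement": {
    "BP": {"both_accept": 162, "both_reject": 39, "split": 41},
    "D": {"both_accept": 152, "both_reject": 48, "split": 42}
  },
  "concept_review": {
    "BP": {"total": 3175, "accepted": 699, "modified": 413, "rejected": 2061},
    "D": {"total": 4967, "accepted": 1094, "modified": 146, "rejected": 3727}
  },
  "common_term_counts": {
    "BP": {"with_common": 42, "total": 45},
    "D": {"with_common": 48, "total": 51}
  },
  "terms_per_abstract": {
    "BP": {"system": 6.2, "curator": 2.4, "common": 1.1},
    "D": {"system": 6.0, "curator": 1.5, "common": 1.2}
  },
  "rank_precision": {
    "BP": {"baseline_p0": 0.48, "baseline_p5": 0.28, "reranked_p0": 0.63, "reranked_p5": 0.35},
    "D": {"baseline_p0": 0.48, "baseline_p5": 0.17, "reranked_p0": 0.59, "reranked_p5": 0.22}
  }
}
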
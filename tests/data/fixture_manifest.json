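{
 "biomarkers_colon_M0N": {
  "lncRNA": 4,
  "miRNA": 1
 },
 "biomarkers_colon_M1N": {
  "lncRNA": 4,
  "miRNA": 1
 },
 "biomarkers_rectal_M0N": {
  "lncRNA": 4,
  "miRNA": 1
 },
 "biomarkers_rectal_M1N": {
  "lncRNA": 4,
  "miRNA": 1
 },
 "catalog_edges": 1766,
 "config_digest": "aae1612b3239",
 "context_colon_M0N": {
  "candidates": 252,
  "nodes": 111,
  "triplets": 252
 },
 "context_colon_M1N": {
  "candidates": 252,
  "nodes": 107,
  "triplets": 250
 },
 "context_rectal_M0N": {
  "candidates": 252,
  "nodes": 111,
  "triplets": 252
 },
 "context_rectal_M1N": {
  "candidates": 243,
  "nodes": 104,
  "triplets": 239
 },
 "de_colon_M0N": {
  "lncRNA": 32,
  "mRNA": 100,
  "miRNA": 39
 },
 "de_colon_M1N": {
  "lncRNA": 32,
  "mRNA": 110,
  "miRNA": 39
 },
 "de_common_lncRNA": 31,
 "de_common_mRNA": 87,
 "de_common_miRNA": 39,
 "de_rectal_M0N": {
  "lncRNA": 32,
  "mRNA": 90,
  "miRNA": 39
 },
 "de_rectal_M1N": {
  "lncRNA": 31,
  "mRNA": 97,
  "miRNA": 39
 },
 "global_triplets": 272,
 "hubs_colon_M0N": 6,
 "hubs_colon_M1N": 6,
 "hubs_rectal_M0N": 6,
 "hubs_rectal_M1N": 6,
 "key_triplets_colon_M0N": 2,
 "key_triplets_colon_M1N": 2,
 "key_triplets_rectal_M0N": 2,
 "key_triplets_rectal_M1N": 2,
 "pairs_significant": 50,
 "pairs_tested": 6625,
 "shared_triplets": 237
}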
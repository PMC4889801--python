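{
 "category_names": ["Viral fever", "Malaria", "Typhoid", "Stomach problem", "Chest problem"],
 "feature_names": ["Temperature", "Headache", "Stomach pain", "Cough", "Chest pain"],
 "samples": [
  {"label": 2, "name": "Al",
   "triples": [[0.8, 0.1, 0.1], [0.6, 0.1, 0.3], [0.2, 0.8, 0.0], [0.6, 0.1, 0.3], [0.1, 0.6, 0.3]]},
  {"label": 4, "name": "Bob",
   "triples": [[0.0, 0.8, 0.2], [0.4, 0.4, 0.2], [0.6, 0.1, 0.3], [0.1, 0.7, 0.2], [0.1, 0.8, 0.1]]},
  {"label": 3, "name": "Joe",
   "triples": [[0.8, 0.1, 0.1], [0.8, 0.1, 0.1], [0.0, 0.6, 0.4], [0.2, 0.7, 0.1], [0.0, 0.5, 0.5]]},
  {"label": 2, "name": "Ted",
   "triples": [[0.6, 0.1, 0.3], [0.5, 0.4, 0.1], [0.3, 0.4, 0.3], [0.7, 0.2, 0.1], [0.3, 0.4, 0.3]]}
 ]
}
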
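{
 "category_names": ["Viral fever", "Malaria", "Typhoid", "Stomach problem", "Chest problem"],
 "feature_names": ["Temperature", "Headache", "Stomach pain", "Cough", "Chest pain"],
 "samples": [
  {"label": 1, "name": "Viral fever",
   "triples": [[0.4, 0.0, 0.6], [0.3, 0.5, 0.2], [0.1, 0.7, 0.2], [0.4, 0.3, 0.3], [0.1, 0.7, 0.2]]},
  {"label": 2, "name": "Malaria",
   "triples": [[0.7, 0.0, 0.3], [0.2, 0.6, 0.2], [0.0, 0.9, 0.1], [0.7, 0.0, 0.3], [0.1, 0.8, 0.1]]},
  {"label": 3, "name": "Typhoid",
   "triples": [[0.3, 0.3, 0.4], [0.6, 0.1, 0.3], [0.2, 0.7, 0.1], [0.2, 0.6, 0.2], [0.1, 0.9, 0.0]]},
  {"label": 4, "name": "Stomach problem",
   "triples": [[0.1, 0.7, 0.2], [0.2, 0.4, 0.4], [0.8, 0.0, 0.2], [0.2, 0.7, 0.1], [0.5, 0.7, 0.1]]},
  {"label": 5, "name": "Chest problem",
   "triples": [[0.1, 0.8, 0.1], [0.0, 0.8, 0.0], [0.2, 0.8, 0.0], [0.2, 0.8, 0.0], [0.8, 0.1, 0.1]]},
  {"label": 1, "name": "Ted",
   "triples": [[0.6, 0.1, 0.3], [0.5, 0.4, 0.1], [0.3, 0.4, 0.3], [0.7, 0.2, 0.1], [0.3, 0.4, 0.3]]},
  {"label": 2, "name": "Al",
   "triples": [[0.8, 0.1, 0.1], [0.6, 0.1, 0.3], [0.2, 0.8, 0.0], [0.6, 0.1, 0.3], [0.1, 0.6, 0.3]]},
  {"label": 3, "name": "Joe",
   "triples": [[0.8, 0.1, 0.1], [0.8, 0.1, 0.1], [0.0, 0.6, 0.4], [0.2, 0.7, 0.1], [0.0, 0.5, 0.5]]},
  {"label": 4, "name": "Bob",
   "triples": [[0.0, 0.8, 0.2], [0.4, 0.4, 0.2], [0.6, 0.1, 0.3], [0.1, 0.7, 0.2], [0.1, 0.8, 0.1]]}
 ]
}
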
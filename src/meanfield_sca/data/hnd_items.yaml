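# HowNutsAreTheDutch (HND) item subset: 21 mood items plus appetite and
# laughter, each on a continuous 0-100 scale. Items flagged reversed are the
# positively worded ones, recoded x -> 100 - x before the median split so
# that high values indicate more negative affect throughout. The published
# description says ten positive items were recoded without enumerating them;
# the default set below is this package's reading (the ten positively worded
# mood items) and can be overridden in the pipeline configuration.
questionnaire: HND
scale: continuous
items:
  - {id: 1,  label: "I feel relaxed",                 reversed: true}
  - {id: 2,  label: "I feel gloomy",                  reversed: false}
  - {id: 3,  label: "I feel energetic",               reversed: true}
  - {id: 4,  label: "I feel anxious",                 reversed: false}
  - {id: 5,  label: "I feel enthusiastic",            reversed: true}
  - {id: 6,  label: "I feel nervous",                 reversed: false}
  - {id: 7,  label: "I feel content",                 reversed: true}
  - {id: 8,  label: "I feel irritable",               reversed: false}
  - {id: 9,  label: "I feel calm",                    reversed: true}
  - {id: 10, label: "I feel dull",                    reversed: false}
  - {id: 11, label: "I feel cheerful",                reversed: true}
  - {id: 12, label: "I feel tired",                   reversed: false}
  - {id: 13, label: "I feel valued",                  reversed: true}
  - {id: 14, label: "I feel lonely",                  reversed: false}
  - {id: 15, label: "I feel I fall short",            reversed: false}
  - {id: 16, label: "I feel confident",               reversed: true}
  - {id: 17, label: "I worry a lot",                  reversed: false}
  - {id: 18, label: "I am easily distracted",         reversed: false}
  - {id: 19, label: "I feel my life is worth living", reversed: true}
  - {id: 20, label: "I am unbalanced",                reversed: false}
  - {id: 21, label: "I am in the here and now",       reversed: true}
  - {id: 22, label: "My appetite",                    reversed: false}
  - {id: 23, label: "Since the last measurement I had a laugh", reversed: false}
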
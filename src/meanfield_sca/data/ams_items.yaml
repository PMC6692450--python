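# Adjective Mood Scale (AMS): 28 forced-choice items. Each response is
# tri-state, already coded 0 = positive pole, 1 = neither, 2 = negative pole.
# "reversed" records which items were presented with a reversed response
# scale in the original questionnaire (the coded values above are already
# normalized, so no recoding is needed at analysis time).
questionnaire: AMS
scale: tristate
items:
  - {id: 1,  positive: openly,          negative: inhibited,     reversed: true}
  - {id: 2,  positive: good mood,       negative: bad mood,      reversed: true}
  - {id: 3,  positive: active,          negative: passive,       reversed: false}
  - {id: 4,  positive: healthy,         negative: sickly,        reversed: false}
  - {id: 5,  positive: purposefully,    negative: aimlessly,     reversed: true}
  - {id: 6,  positive: humorous,        negative: serious,       reversed: false}
  - {id: 7,  positive: imaginative,     negative: unimaginative, reversed: false}
  - {id: 8,  positive: sensitive,       negative: numb,          reversed: true}
  - {id: 9,  positive: optimistic,      negative: pessimistic,   reversed: false}
  - {id: 10, positive: carefree,        negative: worried,       reversed: true}
  - {id: 11, positive: cheerful,        negative: broken,        reversed: false}
  - {id: 12, positive: lovingly,        negative: loveless,      reversed: true}
  - {id: 13, positive: innocent,        negative: guilty,        reversed: false}
  - {id: 14, positive: rested,          negative: tired,         reversed: false}
  - {id: 15, positive: lively,          negative: life-tired,    reversed: false}
  - {id: 16, positive: good,            negative: bad,           reversed: true}
  - {id: 17, positive: cheerful,        negative: tearful,       reversed: true}
  - {id: 18, positive: loved,           negative: unloved,       reversed: true}
  - {id: 19, positive: energetic,       negative: lacking in energy, reversed: false}
  - {id: 20, positive: sociable,        negative: withdrawn,     reversed: false}
  - {id: 21, positive: lively,          negative: sluggish,      reversed: true}
  - {id: 22, positive: temperamentfull, negative: lifeless,      reversed: true}
  - {id: 23, positive: watchful,        negative: absent,        reversed: true}
  - {id: 24, positive: hopeful,         negative: desperate,     reversed: false}
  - {id: 25, positive: satisfied,       negative: dissatisfied,  reversed: true}
  - {id: 26, positive: combative,       negative: anxious,       reversed: false}
  - {id: 27, positive: powerful,        negative: powerless,     reversed: true}
  - {id: 28, positive: balanced,        negative: agitated,      reversed: true}
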
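# Cue lexicon for classifying answers to the depression-diagnosis question
# into yes / no / other.  This rule set is a reconstruction: the source
# corpus's annotation guidelines for this question are not public, so the
# lists are editable and intentionally conservative (anything that does not
# hit a cue is "other").

yes_cues:
  - "yes"
  - "yeah"
  - "yep"
  - "yup"
  - "definitely"
  - "absolutely"
  - "affirmative"

no_cues:
  - "no"
  - "nope"
  - "nah"
  - "never"
  - "negative"

# Negation tokens checked in a 3-token look-back window before a yes-cue.
negations:
  - "not"
  - "don't"
  - "dont"
  - "didn't"
  - "didnt"
  - "haven't"
  - "havent"
  - "wasn't"
  - "wasnt"
  - "wouldn't"
  - "wouldnt"
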
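# Cue phrases for rhetorical zone boundaries and patient-context detection.
# Lists are illustrative-extendable: add phrases without touching code.
method_cues:
  - we have analyzed
  - we have analysed
  - we analyzed
  - we analysed
  - we studied
  - our aim is to
  - our aim was to
  - we aimed
  - we used
  - we use
  - we applied
  - we screened
  - we examined
  - we investigated
  - we performed
  - we conducted
  - we genotyped
  - we sequenced
  - we recruited
  - we enrolled
  - we evaluated
  - we assessed
  - we tested
  - this study was designed
  - the aim of this study
  - the purpose of this study
  - to investigate whether
  - were genotyped
  - were recruited
  - were enrolled
result_cues:
  - we found that
  - the results indicate that
  - the results indicated that
  - the results show
  - the results showed
  - our findings exhibit that
  - our findings show
  - our findings indicate
  - we have shown that
  - we have found
  - we have identified
  - we identified
  - we found
  - we observed
  - we detected
  - was found to
  - were found to
  - was significantly
  - were significantly
  - significantly associated
  - significantly increased
  - significantly decreased
conclusion_cues:
  - in conclusion
  - we conclude by
  - we conclude that
  - in summary
  - taken together
  - our results suggest
  - our data suggest
  - these findings suggest
  - these results suggest
  - this study suggests
  - our study suggests
  - these data indicate
patient_nouns:
  - patients
  - patient
  - controls
  - control
  - cases
  - subjects
  - participants
  - families
  - volunteers
  - men
  - women
  - individuals
cohort_verbs:
  - enrolled
  - recruited
  - included
  - registered
  - analyzed
  - analysed
  - examined
  - studied
  - genotyped
  - screened
  - investigated
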
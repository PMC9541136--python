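# The 17 signalling questions of the risk-of-bias assessment.
# Prompts are paraphrases maintained as editable data; ids are stable and
# must never be renumbered. Section layout: 4 research-statement questions,
# 1 resolution statement, then representativeness / temporal-consistency /
# mitigation triples for the geographic, environmental and taxonomic
# domains, and an other-biases triple.
- id: "1.1"
  section: research_statement
  role: scope
  prompt: >-
    Define the statistical target population about which inferences are
    desired: the extents of every relevant domain (geographic, temporal,
    taxonomic, environmental) and the resolutions (grain sizes) at which
    the analysis will be conducted.
- id: "1.2"
  section: research_statement
  role: scope
  prompt: >-
    State the inferential goal of the study (for example, to estimate
    temporal trends in species' occupancy across the declared extent).
- id: "1.3"
  section: research_statement
  role: provenance
  prompt: >-
    Document the provenances of all datasets used: where each came from,
    when it was obtained, and under what sampling or aggregation process
    it was generated.
- id: "1.4"
  section: research_statement
  role: provenance
  prompt: >-
    Explain and justify every step taken to modify or clean the data,
    including how many records each step removed or altered.
- id: "2.1"
  section: resolution
  role: scope
  prompt: >-
    Specify the geographic, temporal and taxonomic resolutions (grain
    sizes) at which this bias assessment is conducted, and how they relate
    to the resolutions at which inferences will be stated.
- id: "2.2"
  section: geographic
  role: representativeness
  prompt: >-
    Are the data representative of the geographic domain of the target
    population — do records cover the whole extent evenly (ideally as a
    random sample would)?
- id: "2.3"
  section: geographic
  role: temporal_consistency
  prompt: >-
    Has the same portion of geographic space been sampled over time, or is
    there evidence that spatial coverage shifts between periods (so that
    shifts in space are confounded with shifts in time)?
- id: "2.4"
  section: geographic
  role: mitigation
  prompt: >-
    If geographic biases were indicated above, how will they be mitigated,
    or why are they not relevant to the inferential goal?
- id: "2.5"
  section: environmental
  role: representativeness
  prompt: >-
    Are the data representative of the environmental space of the target
    population (for example, the climatic conditions realized across the
    declared extent)?
- id: "2.6"
  section: environmental
  role: temporal_consistency
  prompt: >-
    Has the same portion of environmental space been sampled over time, or
    does environmental coverage shift between periods?
- id: "2.7"
  section: environmental
  role: mitigation
  prompt: >-
    If environmental biases were indicated above, how will they be
    mitigated, or why are they not relevant to the inferential goal?
- id: "2.8"
  section: taxonomic
  role: representativeness
  prompt: >-
    Are the data representative of the taxonomic (or other organismal)
    domain of the target population — are all target taxa recorded, and
    how evenly are records spread across them?
- id: "2.9"
  section: taxonomic
  role: temporal_consistency
  prompt: >-
    Has the same portion of the taxonomic domain been sampled over time,
    or does the recorded taxon set turn over between periods?
- id: "2.10"
  section: taxonomic
  role: mitigation
  prompt: >-
    If taxonomic biases were indicated above, how will they be mitigated,
    or why are they not relevant to the inferential goal?
- id: "2.11"
  section: other
  role: other_bias
  prompt: >-
    Are there other potential biases relevant to the inferential goal that
    the previous domains do not capture (for example, changes in recording
    effort, detectability or protocols)?
- id: "2.12"
  section: other
  role: other_bias
  prompt: >-
    Is there any indication that such other biases vary over time?
- id: "2.13"
  section: other
  role: mitigation
  prompt: >-
    If other biases were indicated above, how will they be mitigated, or
    why are they not relevant to the inferential goal?
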
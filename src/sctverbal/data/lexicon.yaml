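# Verbalization lexicon: one entry per relationship type the generator
# knows how to phrase. Entries are grouped rhetorically and totally
# ordered by rank, following the typical flow of a disease description
# in medical reference texts: definition, causes, temporality,
# diagnosis, clinical course, then everything else.
#
# Fields:
#   key        stable relationship-type key used throughout the code
#   group      rhetorical group
#   rank       total order over entries; sentences are emitted in rank order
#   type_ids   SNOMED CT attribute concept ids mapped onto this entry
#              (empty for the two structural entries: children, other)
#   type_name  human-readable attribute name, used in structured-content output
#   pattern    the fixed lexical cue every realized sentence must contain
#   template   full sentence template; placeholders: {title} {name} {targets}
- key: is_a
  group: Definition
  rank: 1
  type_ids: ["116680003"]
  type_name: "Is a"
  pattern: "is a kind of"
  template: "{title} is a kind of {targets}."
- key: finding_site
  group: Definition
  rank: 2
  type_ids: ["363698007"]
  type_name: "Finding site"
  pattern: "that affects"
  template: "{title} is a condition that affects {targets}."
- key: has_definitional_manifestation
  group: Definition
  rank: 3
  type_ids: ["363705008"]
  type_name: "Has definitional manifestation"
  pattern: "manifests itself in"
  template: "It manifests itself in {targets}."
- key: associated_morphology
  group: Definition
  rank: 4
  type_ids: ["116676008"]
  type_name: "Associated morphology"
  pattern: "The associated morphology is"
  template: "The associated morphology is {targets}."
- key: pathological_process
  group: Definition
  rank: 5
  type_ids: ["370135005"]
  type_name: "Pathological process"
  pattern: "Pathological process associated with"
  template: "Pathological process associated with {name} is {targets}."
- key: children
  group: Definition
  rank: 6
  type_ids: []
  type_name: "Is a"
  pattern: "xample"
  template: "Some examples of {name} are {targets}."
  template_singular: "An example of {name} is {targets}."
- key: causative_agent
  group: Causality
  rank: 7
  type_ids: ["246075003"]
  type_name: "Causative agent"
  pattern: "is caused by"
  template: "It is caused by {targets}."
- key: due_to
  group: Causality
  rank: 8
  type_ids: ["42752001"]
  type_name: "Due to"
  pattern: "occurs due to"
  template: "It occurs due to {targets}."
- key: associated_with
  group: Causality
  rank: 9
  type_ids: ["47429007"]
  type_name: "Associated with"
  pattern: "is associated with"
  template: "It is associated with {targets}."
- key: occurrence
  group: Temporality
  rank: 10
  type_ids: ["246454002"]
  type_name: "Occurrence"
  pattern: "presents in"
  template: "It presents in {targets}."
- key: during_following_after
  group: Temporality
  rank: 11
  type_ids: ["371881003", "255234002", "363708005"]
  type_name: "During or following"
  pattern: "can occur during or following"
  template: "It can occur during or following {targets}."
- key: temporally_related
  group: Temporality
  rank: 12
  type_ids: ["726633004"]
  type_name: "Temporally related to"
  pattern: "can be temporally related to"
  template: "It can be temporally related to {targets}."
- key: finding_method
  group: Diagnosis
  rank: 13
  type_ids: ["418775008"]
  type_name: "Finding method"
  pattern: "is discovered by"
  template: "It is discovered by {targets}."
- key: finding_informer
  group: Diagnosis
  rank: 14
  type_ids: ["419066007"]
  type_name: "Finding informer"
  pattern: "is discovered through"
  template: "It is discovered through {targets}."
- key: clinical_course
  group: ClinicalCourse
  rank: 15
  type_ids: ["263502005"]
  type_name: "Clinical course"
  pattern: "Clinical course is"
  template: "Clinical course is {targets}."
- key: severity
  group: ClinicalCourse
  rank: 16
  type_ids: ["246112005"]
  type_name: "Severity"
  pattern: "The severity of"
  template: "The severity of {name} is {targets}."
- key: episodicity
  group: ClinicalCourse
  rank: 17
  type_ids: ["246456000"]
  type_name: "Episodicity"
  pattern: "The episodicity of"
  template: "The episodicity of {name} is {targets}."
- key: interprets
  group: Other
  rank: 18
  type_ids: ["363714003"]
  type_name: "Interprets"
  pattern: "interprets or evaluates"
  template: "It interprets or evaluates {targets}."
- key: has_interpretation
  group: Other
  rank: 19
  type_ids: ["363713009"]
  type_name: "Has interpretation"
  pattern: "is interpreted as"
  template: "It is interpreted as {targets}."
- key: other
  group: Other
  rank: 20
  type_ids: []
  type_name: "Other"
  pattern: "Other related concepts include"
  template: "Other related concepts include {targets}."
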
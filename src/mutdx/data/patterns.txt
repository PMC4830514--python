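# Sentence-structure patterns for mutation-disease pairing.
# Syntax: [category] sections, "trigger:" declarations, one pattern per
# line.  NP{head: w}, NP{contains: w}, NP<mutation>, NP<disease>,
# VG_active{head: w}, VG_passive{head: w}; "a/b" expands to variants.

[association]
trigger: associate
NP1 VG_passive{head: associate} with NP2
NP1 VG_active{head: associate} with NP2
NP{head: associate} of NP1 with/and NP2
NP{head: associate} between NP1 and NP2

trigger: correlate
NP1 VG_passive{head: correlate} with/to NP2
NP1 VG_active{head: correlate} with NP2
NP{head: correlate} between NP1 and NP2
NP{head: correlate} of NP1 with/to NP2

trigger: contribute
NP1 VG_active{head: contribute} to NP2
NP{head: contribute} of NP1 to NP2

trigger: relationship
NP{head: relationship} between NP1 and NP2
NP{head: relationship} of NP1 with/to NP2

trigger: effect
NP{head: effect} of NP1 in/on NP2

[comparison]
trigger: compare
VG_active{head: compare} to/with NP1 , NP2 VG_active NP{contains: more/less} in NP3

trigger: difference
NP1 VG_active NP{head: difference} between NP2 and NP3

[mutation_found]
trigger: detect
NP{head: detect} of NP<mutation>
NP<mutation> VG_passive{head: detect}
VG_active{head: detect} NP<mutation>

trigger: identify
NP{head: identify} of NP<mutation>
NP<mutation> VG_passive{head: identify}
VG_active{head: identify} NP<mutation>

trigger: find
NP<mutation> VG_passive{head: find}
VG_active{head: find} NP<mutation>

trigger: analyze
NP<mutation> VG_passive{head: analyze}
VG_active{head: analyze} NP<mutation>

trigger: screen
NP<mutation> VG_passive{head: screen}
VG_active{head: screen} for NP<mutation>
NP{head: screen} for NP<mutation>
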
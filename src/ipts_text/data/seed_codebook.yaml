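# Seed phrase codebooks for the four IPTS dimensions and acquired capability.
# These are the starting points of iterative codebook expansion; seeds are
# always retained. Dimension ids are the canonical ones used throughout the
# package: loneliness + lack_love compose thwarted belongingness, self_hate +
# liability compose perceived burdensomeness, capability is scored directly.
loneliness:
  - disconnected
  - loneliness
  - pulling together
  - no care
  - seasonal variation
  - reductions in social interactions
  - marriage
  - no children and friends
  - living alone
  - no social supports
lack_love:
  - lack love
  - no love
  - social withdrawal
  - low openness
  - single jail cell
  - domestic violence
  - childhood abuse
  - familial discord
self_hate:
  - i hate myself
  - i am useless
  - low self-esteem
  - self-blame
  - shame
  - mental state of agitation
liability:
  - my death is worth more than my life
  - distress from homelessness
  - distress from incarceration
  - distress from unemployment
  - distress from physical illness
  - expendability
  - unwanted
  - belief of burden on family
capability:
  - increased physical pain tolerance
  - reduced fear of death
  - habituation
  - physical pain
  - acquired capability
  - lowered fear of death
  - past serious ideation
  - non-zero degree of fearlessness
  - courage and the ability to commit suicide
  - elevated physical pain tolerance
  - recent suicidal behavior
  - serious levels of suicidal intent
  - cutting one's wrists
  - pulling the trigger on a gun
  - jumping off a building
  - overdose
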
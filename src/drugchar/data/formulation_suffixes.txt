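# Trade-name formulation suffixes stripped by normalize_trade_name.
# One term per line; '#' starts a comment.  Editable / overridable.
sr
cr
xr
xl
la
mr
er
ir
forte
plus
duo
retard
depot
syrup
elixir
suspension
solution
tablet
tablets
capsule
capsules
caplets
injection
infusion
cream
ointment
gel
lotion
drops
spray
inhaler
patch
patches
suppository
suppositories
sachet
sachets
wafer
wafers
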
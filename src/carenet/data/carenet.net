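# CARENET: cambium regulation gene network (30 nodes).
#
# Control nodes are external hormonal/peptidic inputs fixed per run:
#   CK0  external cytokinin        IAA0  external auxin
#   BR   brassinosteroids          GA    gibberellic acid
#   TDIF CLE41/42/44 peptide       ETHL  ethylene
# Internal nodes are genes/proteins/processes of the cytokinin, auxin,
# ethylene, brassinosteroid and TDIF/PXY signalling pathways; WOX4 and
# HB8 (ATHB8) are the proliferation reporters, ENDO denotes endocytosis.
#
# The edge list is curated from the experimental literature on cambium
# and (pro)cambium regulation; edges marked "provisional" rest on the
# weakest evidence and are the first candidates for revision.  The
# network is pure data: correcting an edge requires no code change.

[nodes]
CK0    control
IAA0   control
BR     control
GA     control
TDIF   control
ETHL   control
CK     internal
AHK    internal
AHP    internal
AHP6   internal
RRA    internal
RRB    internal
IPT    internal
LOG    internal
CKX    internal
IAA    internal
ARF    internal
PIN    internal
ENDO   internal
TMO5   internal
LHW    internal
STM    internal
ERF    internal
WRKY   internal
BZR1   internal
BIN2   internal
PXY    internal
WOX4   internal
WOX14  internal
HB8    internal

[edges]
# cytokinin synthesis, perception and feedback
CK0    ->  CK
IPT    ->  CK
LOG    ->  CK
CKX    -|  CK
CK     ->  AHK
AHK    ->  AHP
AHP6   -|  AHP
RRA    -|  AHP
AHP    ->  RRB
RRB    ->  RRA
RRB    ->  CKX     # self-limiting: B-type response regulators induce CKX
RRB    ->  PIN     # cytokinin raises PIN expression, draining auxin
RRB    ->  ERF     # RRB binds the ERF promoter
RRB    ->  ENDO    # provisional ENDO wiring
TMO5   ->  LOG     # TMO5-LHW dimer activates LOG
LHW    ->  LOG
WRKY   ->  LOG
# auxin uptake, signalling and efflux
IAA0   ->  IAA
GA     ->  IAA     # GA raises auxin level in cambium cells
PIN    -|  IAA     # efflux lowers intracellular auxin
IAA    ->  ARF
ARF    ->  AHP6    # auxin dampens cytokinin signalling
ARF    ->  CKX
ARF    -|  IPT
ARF    ->  TMO5
ARF    ->  STM
ARF    ->  PIN
ARF    ->  HB8     # provisional HB8 regulator set
ENDO   -|  PIN
STM    -|  LHW
# ethylene
ETHL   ->  ERF
ERF    ->  WOX4
# brassinosteroid / GA bridge through WRKY
BR     -|  BIN2
BIN2   -|  BZR1
BZR1   ->  WRKY
GA     ->  WRKY
WRKY   ->  ERF
WRKY   -|  CKX     # WRKY represses the cytokinin-degrading enzyme
# TDIF/PXY module
TDIF   ->  PXY
PXY    ->  WOX4
PXY    ->  WOX14
PXY    ->  BIN2
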
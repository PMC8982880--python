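[
 {
  "from": "C",
  "to": "Cp",
  "rate_kind": "d+",
  "scale_name": "x7"
 },
 {
  "from": "Cp",
  "to": "C",
  "rate_kind": "d-",
  "scale_name": "x8"
 },
 {
  "from": "Cp",
  "to": "O",
  "rate_kind": "d+",
  "scale_name": "x7"
 },
 {
  "from": "O",
  "to": "Cp",
  "rate_kind": "d-",
  "scale_name": "x8"
 },
 {
  "from": "If",
  "to": "Ifp",
  "rate_kind": "d+",
  "scale_name": "x7"
 },
 {
  "from": "Ifp",
  "to": "If",
  "rate_kind": "d-",
  "scale_name": "x8"
 },
 {
  "from": "If2",
  "to": "If2p",
  "rate_kind": "d+",
  "scale_name": "x7"
 },
 {
  "from": "If2p",
  "to": "If2",
  "rate_kind": "d-",
  "scale_name": "x8"
 },
 {
  "from": "C",
  "to": "If",
  "rate_kind": "f-",
  "scale_name": "x6"
 },
 {
  "from": "If",
  "to": "C",
  "rate_kind": "f+",
  "scale_name": "x5"
 },
 {
  "from": "Cp",
  "to": "Ifp",
  "rate_kind": "f-",
  "scale_name": "x6"
 },
 {
  "from": "Ifp",
  "to": "Cp",
  "rate_kind": "f+",
  "scale_name": "x5"
 },
 {
  "from": "O",
  "to": "Ifp",
  "rate_kind": "f-",
  "scale_name": "x6"
 },
 {
  "from": "Ifp",
  "to": "O",
  "rate_kind": "f+",
  "scale_name": "x5"
 },
 {
  "from": "C",
  "to": "If",
  "rate_kind": "ca",
  "scale_name": "x2"
 },
 {
  "from": "Cp",
  "to": "Ifp",
  "rate_kind": "ca",
  "scale_name": "x3"
 },
 {
  "from": "O",
  "to": "Ifp",
  "rate_kind": "ca",
  "scale_name": "x4"
 },
 {
  "from": "C",
  "to": "If2",
  "rate_kind": "f2-",
  "scale_name": "x10"
 },
 {
  "from": "If2",
  "to": "C",
  "rate_kind": "f2+",
  "scale_name": "x9"
 },
 {
  "from": "Cp",
  "to": "If2p",
  "rate_kind": "f2-",
  "scale_name": "x10"
 },
 {
  "from": "If2p",
  "to": "Cp",
  "rate_kind": "f2+",
  "scale_name": "x9"
 },
 {
  "from": "O",
  "to": "If2p",
  "rate_kind": "f2-",
  "scale_name": "x10"
 },
 {
  "from": "If2p",
  "to": "O",
  "rate_kind": "f2+",
  "scale_name": "x9"
 }
]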
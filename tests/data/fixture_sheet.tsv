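sample_id	group
case_000	case
case_001	case
case_002	case
case_003	case
case_004	case
case_005	case
ctrl_000	control
ctrl_001	control
ctrl_002	control
ctrl_003	control
ctrl_004	control
ctrl_005	control
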
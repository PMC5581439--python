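# Default glycoside hydrolase family universe (135 families).
GH1
GH2
GH3
GH4
GH5
GH6
GH7
GH8
GH9
GH10
GH11
GH12
GH13
GH14
GH15
GH16
GH17
GH18
GH19
GH20
GH21
GH22
GH23
GH24
GH25
GH26
GH27
GH28
GH29
GH30
GH31
GH32
GH33
GH34
GH35
GH36
GH37
GH38
GH39
GH40
GH41
GH42
GH43
GH44
GH45
GH46
GH47
GH48
GH49
GH50
GH51
GH52
GH53
GH54
GH55
GH56
GH57
GH58
GH59
GH60
GH61
GH62
GH63
GH64
GH65
GH66
GH67
GH68
GH69
GH70
GH71
GH72
GH73
GH74
GH75
GH76
GH77
GH78
GH79
GH80
GH81
GH82
GH83
GH84
GH85
GH86
GH87
GH88
GH89
GH90
GH91
GH92
GH93
GH94
GH95
GH96
GH97
GH98
GH99
GH100
GH101
GH102
GH103
GH104
GH105
GH106
GH107
GH108
GH109
GH110
GH111
GH112
GH113
GH114
GH115
GH116
GH117
GH118
GH119
GH120
GH121
GH122
GH123
GH124
GH125
GH126
GH127
GH128
GH129
GH130
GH131
GH132
GH133
GH134
GH135
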
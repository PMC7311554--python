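item_id,alloc_index,alloc_self,alloc_other
1,1,85,85
1,2,85,76
1,3,85,68
1,4,85,59
1,5,85,50
1,6,85,41
1,7,85,33
1,8,85,24
1,9,85,15
2,1,85,15
2,2,87,19
2,3,89,24
2,4,91,28
2,5,93,33
2,6,94,37
2,7,96,41
2,8,98,46
2,9,100,50
3,1,50,100
3,2,54,98
3,3,59,96
3,4,63,94
3,5,68,93
3,6,72,91
3,7,76,89
3,8,81,87
3,9,85,85
4,1,50,100
4,2,54,89
4,3,59,79
4,4,63,68
4,5,68,58
4,6,72,47
4,7,76,36
4,8,81,26
4,9,85,15
5,1,100,50
5,2,94,56
5,3,88,63
5,4,81,69
5,5,75,75
5,6,69,81
5,7,63,88
5,8,56,94
5,9,50,100
6,1,100,50
6,2,98,54
6,3,96,59
6,4,94,63
6,5,93,68
6,6,91,72
6,7,89,76
6,8,87,81
6,9,85,85
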
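42
0.262602 0.349063 0.195327 0.193008
0.201672 0.313499 0.237756 0.247073
0.393729 0.201338 0.164478 0.240455
0.272247 0.252909 0.237482 0.237362
43
0.326711 0.264852 0.213746 0.194690
0.255871 0.201187 0.326516 0.216426
0.231268 0.156259 0.398030 0.214444
0.307938 0.233993 0.254990 0.203079
44
0.219020 0.223319 0.181315 0.376346
0.227707 0.253228 0.278633 0.240433
0.271800 0.212677 0.219238 0.296286
0.282624 0.144303 0.216767 0.356305
45
0.203266 0.194837 0.309289 0.292608
0.243198 0.234937 0.315690 0.206176
0.214846 0.372427 0.143173 0.269554
0.230008 0.242427 0.229923 0.297642
46
0.273614 0.290846 0.161774 0.273766
0.331568 0.260816 0.265103 0.142513
0.162476 0.220410 0.257395 0.359718
0.186639 0.317558 0.269976 0.225827
47
0.230419 0.228121 0.252926 0.288534
0.259499 0.223147 0.204051 0.313303
0.210403 0.203939 0.319683 0.265975
0.184493 0.240052 0.305449 0.270006
48
0.296168 0.245619 0.282247 0.175966
0.252920 0.170870 0.252532 0.323678
0.215284 0.255465 0.303322 0.225929
0.218502 0.172745 0.305945 0.302808
49
0.215585 0.310201 0.210059 0.264155
0.192355 0.285799 0.269894 0.251952
0.204539 0.190741 0.346570 0.258151
0.334507 0.265693 0.227972 0.171827
50
0.327515 0.182458 0.272828 0.217200
0.207845 0.187347 0.160457 0.444351
0.220752 0.313549 0.238863 0.226835
0.294425 0.275480 0.175632 0.254463
51
0.263730 0.306493 0.268173 0.161603
0.215931 0.315430 0.192987 0.275651
0.225760 0.293356 0.260057 0.220826
0.206449 0.274012 0.288291 0.231248
52
0.143818 0.282057 0.169130 0.404995
0.146585 0.353909 0.261952 0.237554
0.153920 0.262412 0.296603 0.287064
0.239274 0.218175 0.182453 0.360099
53
0.185259 0.304179 0.276224 0.234338
0.248058 0.250755 0.275059 0.226128
0.221646 0.333355 0.316518 0.128482
0.206506 0.272381 0.284015 0.237099
54
0.195425 0.230508 0.272032 0.302035
0.095960 0.327837 0.410714 0.165489
0.204396 0.122633 0.248168 0.424803
0.244134 0.182399 0.360240 0.213226
55
0.141865 0.263952 0.198487 0.395696
0.227742 0.336486 0.272177 0.163595
0.265784 0.196908 0.260221 0.277086
0.282394 0.231313 0.222718 0.263576
56
0.296404 0.214078 0.247837 0.241680
0.251330 0.332027 0.224455 0.192189
0.181703 0.362310 0.177600 0.278387
0.242213 0.310629 0.161859 0.285299
57
0.184261 0.361573 0.190930 0.263236
0.240670 0.262978 0.237551 0.258801
0.139135 0.341695 0.276093 0.243078
0.185241 0.288349 0.372898 0.153511
58
0.239072 0.326510 0.213968 0.220450
0.272202 0.282417 0.205817 0.239564
0.326228 0.344751 0.179500 0.149521
0.187827 0.253027 0.373130 0.186016
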